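# nasalrecon

Virtual reconstruction of external nasal defects from 3D facial surface
scans. The package addresses a recurring problem in digital prosthodontics
and reconstructive surgery: when the external nose is missing (tumour
resection, trauma, infection), preoperative CAD needs a *target reference
face* — an intact 3D face that matches the patient's remaining anatomy in
both shape and spatial position — from which the missing nasal surface can
be copied. Database matching and deformable mean templates give either poor
spatial alignment or non-personalized noses; `nasalrecon` instead learns a
generative model of whole faces and *searches its latent space* for the
face that best explains the defective scan.

It is aimed at researchers in craniofacial imaging and surface-based deep
learning who want a complete, dependency-light, CPU-reproducible pipeline:
every stage — synthetic data, training, fitting, extraction, evaluation —
is a plain Python function with explicit seeds, and the neural network and
its gradients are implemented directly in NumPy.

## Method

All faces share one fixed template topology (equal vertex indices = equal
anatomical locations). The core is an unsupervised mesh autoencoder:

* **Encoder** — a dual-branch graph-convolutional network over the mesh
  adjacency: a *global* branch (three conv + leaky-ReLU + pool stages down
  a vertex-clustering hierarchy, then a linear head on the coarsest-level
  features) and a *local* branch (three convs at full resolution, mean-
  pooled into a linear head), fused by one linear map into a latent code
  `z ∈ R^D` (default `D = 256`).
* **Decoder** — a linear map from `z` to coarsest-level features, copied
  up through the hierarchy and refined by graph convolutions back to
  per-vertex coordinates.
* **Training loss** —

  `L = L_recon + λ · L_reg`,  with
  `L_recon = (1/N) Σ_i ‖x_i − x̂_i‖²` (mean squared vertex distance, mm²)
  and `L_reg = (‖z‖₂ − 1)²`,

  the spherical regularizer drawing latent codes toward the unit
  hypersphere (`λ = 0.01`, Adam, initial learning rate `0.001`,
  train/val/test split `17:2:1`).

After training the encoder is discarded. For a defective face `S1`, the
decoder acts as a face generator `S2 = decode(z)` and the personalized
target reference face is found by jointly optimizing the latent code and
a rigid motion:

`R*, T*, z* = argmin CD(S1, R·S2 + T) + λ·(‖z‖−1)²`,

where `CD(S1, S2) = (1/|S1|) Σ_{x∈S1} min_{y∈S2} ‖x−y‖²` is the
*unidirectional* chamfer distance (nearest neighbours recomputed every
iteration; rotation parameterized as an axis-angle vector). The defect rim
is then projected onto the fitted face and the enclosed region extracted
as the reconstructed nose, which is scored by

* **morphological similarity** — unsigned point-to-surface RMSD
  ("3D surface deviation") and maximum deviation against the ground-truth
  nose, localized to one of nine nasal subunits (dorsum, paired sidewalls,
  tip, columella, paired soft triangles, paired alae);
* **edge fitness** — RMSD ("curve deviation") and maximum between the
  reconstructed nose's edge curve and the defect rim.

Clinical scan populations cannot be redistributed, so the package ships a
synthetic study population: an analytic face template (smooth dome +
Gaussian nose bumps, closed surface, labelled subunits) and a rank-K
smooth-displacement shape model from which corresponded faces are sampled.

## Worked example

```python
import nasalrecon as nr
from nasalrecon import autoencoder, latent_fit, nn

template = nr.make_template(33)                       # 1090 vertices
model = nr.PopulationModel.build(template, seed=5)    # rank-8 shape model
faces = nr.sample_population(template, model, 60, seed=9)

graph = nr.build_face_graph(template.mesh, n_levels=4)
cfg = autoencoder.TrainConfig(epochs=400, seed=2,
                              model_config=nn.ModelConfig(latent_dim=32))
params, history = autoencoder.train(faces, graph, cfg)
print(f"validation recon: {history['val_recon'][-1]:.2f} mm^2")

case = nr.sample_population(template, model, 1, seed=1234)[0]  # unseen face
defect, nose_truth = nr.simulate_defect(case, template)
fit = latent_fit.fit_trf(defect, params, graph,
                         latent_fit.FitConfig(max_iters=300, restarts=1),
                         exclude_mask=template.nose_mask)
nose = nr.extract_nose(fit.trf, defect.defect_curve)
report = nr.surface_deviation(nose, nose_truth,
                              subunits=template.region_labels[template.nose_mask])
print(f"surface deviation {report.rmsd:.2f} mm, "
      f"max {report.max_deviation:.2f} mm at {report.max_label}")
```

Output from this exact script:

```
validation recon: 0.90 mm^2
surface deviation 2.19 mm, max 3.87 mm at nasal_dorsum
```

The validation reconstruction error (0.90 mm² ≈ 0.95 mm RMS per vertex) is
far below the population's per-vertex shape variance (≈ 30 mm²), i.e. the
autoencoder has learned the face manifold; the fitted reconstruction then
recovers the deleted nose of an unseen face to about 2 mm RMS — versus
roughly 8 mm for this case if the undeformed mean template is only rigidly
aligned.

The same pipeline is scriptable from the shell:

```bash
nasalrecon make-data --out data --n 60 --seed 1
nasalrecon train --data data --out model.npz
nasalrecon fit --checkpoint model.npz --template data/template.obj \
               --defect data/face000_defect.obj --out trf.obj
nasalrecon reconstruct --trf trf.obj --defect data/face000_defect.obj --out nose.obj
nasalrecon evaluate --test nose.obj --reference data/face000_nose.obj --out report.json
```

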