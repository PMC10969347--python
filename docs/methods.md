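# Methods

This note documents the models, the numerical choices, and the scope of
the synthetic benchmark, in the order the pipeline runs them.

## Structured meshes and the graph hierarchy

All faces live on one fixed template topology, so vertex `i` denotes the
same anatomical location on every mesh and the autoencoder can treat a
face as a signal on a fixed graph. Graph convolutions use first-order
neighborhood propagation `Y = Â X W + b` with self-loops. The operator
`Â` is produced by *iterated* symmetric degree normalization of `A + I`
(repeat `D^{-1/2}(A+I)D^{-1/2}` until row sums converge), which yields a
symmetric, doubly-stochastic smoothing operator. Compared with one-shot
symmetric normalization this also preserves constant signals exactly
(rows sum to 1), so a rigid translation of the input propagates through
convolution layers without distortion; the iteration converges in a few
dozen rounds at tolerance `1e-13`.

The pooling hierarchy (default 4 levels) is built by one pass of greedy
edge contraction per level, with candidate edges ranked by the quadric
error of their midpoint (plane quadrics accumulated per vertex) — the
standard mesh-simplification ordering — giving roughly 2× coarsening per
level. Pooling averages cluster members; unpooling copies the cluster
value back (copy-up). Pool maps are surjective and cover every fine
vertex exactly once. Coarsening stops with an error if a level would
drop below 4 vertices.

## The autoencoder

Encoder: two branches over centered vertex coordinates (the training-mean
face is subtracted on input and added back on output; losses are
unaffected because they act on coordinate differences).

* Global branch: 3 × [graph conv, leaky-ReLU, pool] with widths
  (16, 32, 64), then a linear head. The head takes the *flattened*
  coarsest-level features rather than their vertex mean: the
  doubly-stochastic convolution operator preserves per-vertex means, so a
  mean-pooled head is nearly blind to the spatial pattern of displacement
  and, in measurements on the synthetic benchmark, capped validation
  reconstruction around 4 mm² while a free-latent decoder fit reached
  0.1–1.2 mm² — the flattened head (the mirror image of the decoder's
  latent-to-coarse-mesh linear map, as in fixed-topology mesh
  autoencoders of the CoMA family) removes that bottleneck.
* Local branch: 3 × [graph conv, leaky-ReLU] at full resolution with the
  same widths, mean-pooled into a linear head (local features are
  averaged precisely because their *pattern* is the global branch's job).
* Fusion: the two 64-wide heads are concatenated and mapped by one linear
  layer to the latent code `z` (default D = 256; the scaled benchmark
  uses D = 32).

Decoder: one linear map from `z` to coarsest-level features (width 64),
then [unpool, conv, leaky-ReLU] × 2 and a final unpool + conv to 3
coordinates. Leaky-ReLU slope is 0.01 everywhere. The final conv weights
are initialized 10× smaller than Glorot so the untrained decoder starts
near the reference face.

The network and its exact gradients are implemented in NumPy; every
layer's backward pass is verified against central finite differences in
the test suite (relative error ~1e-8). Because each batch shares one
topology, a sparse operator is applied to a whole batch with a single
sparse–dense product, which keeps CPU training fast (≈ 0.4 s/epoch at
1090 vertices × 51 faces).

Training minimizes `L_recon + λ·L_reg` with Adam. `L_recon` is the
*mean* over vertices of squared inter-vertex distance: "MSE" and "sum of
squared distances" disagree by a factor N, and the mean keeps λ
meaningful across template resolutions (a uniform 1 mm offset costs
exactly 1 mm²). `L_reg = (‖z‖−1)²` draws codes toward the unit
hypersphere. Defaults: λ = 0.01, learning rate 0.001, batch 8, split
17:2:1 (round to nearest, remainder to training), early stopping on
validation plateau (patience 50) with the best-validation weights
restored, and a reduce-on-plateau learning-rate halving (patience 20).
Divergence (non-finite loss) aborts with a diagnostic. Training is
deterministic for a fixed seed and thread configuration.

## Latent/rigid fitting

Given defect vertices S1 (all of them; no subsampling at these
resolutions), the fit minimizes the unidirectional chamfer distance from
S1 to the rigidly transformed decoded face plus `λ·(‖z‖−1)²`, jointly
over `z`, an axis-angle rotation vector, and a translation — joint
rather than alternating, since all three gradients come from the same
correspondences. Nearest neighbors are recomputed every iteration
(kd-tree). Numerical choices:

* The rotation acts about the fixed centroid of the reference face (a
  constant independent of `z`), which decouples the rotation and
  translation parameters; the result is converted to standard `Rp + T`
  form on output.
* Rotation derivatives use the closed-form differential of the
  exponential map (skew generators at the origin).
* Initialization: `z` uniform on the unit hypersphere (seeded), R = I,
  T = centroid(S1) − centroid(decoded face outside the template nose
  mask) when the mask is available (otherwise the full face), so the
  generated face starts at the defect's spatial position.
* Adam at learning rate 0.02, halved after 50 iterations without
  improvement; convergence is declared after 20 consecutive relative
  objective changes below 1e-6; max 500 iterations; 3 restarts by
  default, best final objective kept. The reported transform/latent is
  the best *iterate*, not the last, so the minimum of the objective
  history equals the reported objective.

A rigid-only variant of the same descent aligns the undeformed mean
template to the defect; the experiment uses it as the "non-personalized"
baseline.

## Nose extraction

The defect rim is projected point-by-point onto the fitted face
(point-to-triangle closest point, exact over all candidate triangles,
ties to the lowest triangle index; degenerate consecutive duplicates are
merged). The projected curve is then traced on the face's vertex graph
(nearest vertex per curve point, shortest Euclidean-weighted paths
between consecutive anchors), the traced cycle is removed, and the
enclosed region is the union of components not containing the exterior
anchor — by default the vertex farthest from the curve, which on a
face-shaped surface is always far outside the nose. Faces are kept only
when all three vertices are enclosed, so extracting from the intact
source face reproduces the deleted nose exactly (vertex-set equality);
the extracted submesh always has a single boundary loop.

## Deviation metrics

* Surface deviation: unsigned point-to-surface distance from each test
  vertex to the reference mesh (closest point on any triangle, not
  vertex-to-vertex). RMSD and maximum are reported; the maximum is
  localized to the nasal subunit of the reference vertex nearest the
  worst test point. The direction is reconstruction → ground truth; the
  metric is deliberately asymmetric and a fixture in the tests pins the
  direction.
* Curve deviation: both closed curves are resampled to `n_samples = 200`
  points uniformly by arc length; each resampled nose-edge point is
  paired with the closest point on the defect-edge *polyline*
  (continuous along segments, not vertex-snapped). RMSD and maximum of
  the pair distances are reported. Refining `n_samples` changes the RMSD
  by well under 5% on the benchmark fixtures.
* Case series are summarized as mean ± sample standard deviation (n−1)
  plus the tally of max-deviation subunit locations.

## The synthetic study population

Clinical scan datasets cannot be redistributed, so the benchmark
emulates their structure analytically:

* Template: a smooth convex dome (Gaussian in the parametric chart) with
  a protruding nose built from anisotropic Gaussian bumps (dorsal ridge,
  tip, paired alae, columella), triangulated as a regular grid over
  [−1, 1]² (face half-width 70 mm, half-height 90 mm) and closed at the
  back by a single apex vertex so that the only boundary loop of a
  defective face is the defect rim itself. The template is bilaterally
  symmetric; the nine nasal subunits are assigned from the parametric
  zones of the bump construction and are all present from the minimum
  resolution (16) upward. The default resolution 33 gives 1090 vertices —
  a deliberate ~9× reduction from clinical scan density so the whole
  pipeline runs in minutes on one CPU.
* Shape variation: a rank-K Gaussian model (default K = 8). Each basis
  field is white per-vertex noise diffused by 60 rounds of neighborhood
  averaging and normalized to unit RMS vertex displacement; fields are
  global and smooth (max per-edge difference ≤ 1 per unit RMS, typically
  ≈ 0.6, the largest values at the back apex where edges are ~70 mm
  long). Faces are template + Σ c_k·basis_k with c_k ~ N(0, s_k²),
  s = 3.0 → 0.5 mm (linear), chosen to span the few-millimetre
  inter-individual variation reported for facial soft tissue while
  guaranteeing self-intersection-free samples (a guard rejects scales
  above 5% of the template bounding-box diagonal).
* Defect: the "full nasal defect" deletes all nine subunit regions —
  parametrically, above the nasal root, inside the inner canthi, below
  the columella — plus incident triangles, leaving surviving coordinates
  untouched. The deleted submesh is kept as ground truth.

What the generator does *not* emulate: scanner noise and holes,
non-Gaussian and asymmetric anatomy, correspondence error from non-rigid
registration, and texture. Passing tests therefore demonstrate the
pipeline's correctness and its personalization advantage on smooth
low-rank populations, not clinical-grade accuracy; absolute deviation
values are not comparable to values measured on real scans. One known
systematic: because faces are kept only when fully enclosed, the
reconstructed nose's edge sits one vertex ring inside the defect rim, so
the curve-deviation statistics include a fixed ~5 mm discretization
offset at the default resolution. Both pipeline arms (personalized and
baseline) share it, leaving the paired comparison meaningful.

## Scaled benchmark conditions

The default experiment (`ExperimentConfig`): 60 training faces (split
51/6/3), 20 freshly sampled held-out defect cases, D = 32, widths
(16, 32, 64), up to 300 epochs with early stopping, fit with 300
iterations and 1 restart per case. Every stage seed derives from the one
experiment seed, so reports reproduce bit-for-bit. On one CPU the whole
experiment takes ≈ 2 minutes. Under these conditions the autoencoder
reaches validation reconstruction ≈ 0.7–0.9 mm² against a population
variance of ≈ 30 mm², and the personalized reconstruction beats the
rigidly aligned mean template in 20/20 paired cases (mean surface
deviation ≈ 0.23 mm vs ≈ 4.3 mm).

## Known limitations

* The encoder is used only for training; fitting ignores it, so the fit
  inherits chamfer's blindness to unmatched generator regions — the
  spherical regularizer and the decoder's learned manifold are the only
  constraints on the nose region.
* Latent norms settle toward the unit sphere slowly (the regularizer's
  gradient is O(λ)); after early stopping on the scaled benchmark the
  mean norm deviation has typically fallen by half but has not reached
  its asymptote.
* The region-selection cut is a nearest-vertex approximation of the
  projected curve; on very coarse meshes or strongly deformed fits the
  enclosed region can differ by one vertex ring from the intended cut.
* Quadric-ordered matching coarsens by at most 2× per level; level
  counts other than 4 are supported but the encoder/decoder widths
  assume three pooling stages.
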