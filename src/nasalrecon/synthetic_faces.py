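"""Synthetic structured-face population and simulated full nasal defects.

Real clinical face scans are not shippable, so this module generates a
stand-in study population with the same *structure*: a fixed-topology
face-like template (a smooth dome with a protruding nose built from
anisotropic Gaussian bumps, closed at the back), a low-rank smooth
displacement model emulating inter-individual shape variation, and a
parameterized "full nasal defect" that removes the nose region — above
the nasal root, bilaterally inside the inner canthus and below the
columella — leaving a single defect rim.

All stochastic operations take explicit seeds; nothing touches global
RNG state.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp

from .geometry import RigidTransform, axis_angle_to_matrix
from .mesh_core import (
    BoundaryCurve,
    MeshTopologyError,
    StructuredMesh,
    adjacency_matrix,
    boundary_loops,
    extract_boundary,
    mesh_edges,
    submesh,
)

__all__ = [
    "NASAL_SUBUNITS",
    "NON_NASAL",
    "FaceTemplate",
    "PopulationModel",
    "DefectiveFace",
    "make_template",
    "sample_population",
    "simulate_defect",
    "apply_random_rigid",
]

#: The nine anatomical subunits of the external nose used to localize the
#: maximum surface deviation, plus the non-nasal remainder of the face.
NASAL_SUBUNITS = (
    "nasal_dorsum",
    "nasal_sidewall_L",
    "nasal_sidewall_R",
    "nasal_tip",
    "nasal_columella",
    "soft_triangle_L",
    "soft_triangle_R",
    "nasal_ala_L",
    "nasal_ala_R",
)
NON_NASAL = "non_nasal"

# Parametric extent of the full nasal defect in the template's (u, v)
# chart: half-width to the inner canthi and the root-to-columella span.
_U_NOSE = 0.20
_V_NOSE_TOP = 0.30
_V_NOSE_BOT = -0.30


@dataclasses.dataclass
class FaceTemplate:
    """The shared template: mesh, per-vertex subunit labels, nose mask."""

    mesh: StructuredMesh
    region_labels: np.ndarray  # (N,) strings from NASAL_SUBUNITS + NON_NASAL
    nose_mask: np.ndarray  # (N,) bool, True on all nine nasal subunits

    def __post_init__(self) -> None:
        self.region_labels = np.asarray(self.region_labels, dtype=object)
        self.nose_mask = np.asarray(self.nose_mask, dtype=bool)
        if len(self.region_labels) != self.mesh.n_vertices:
            raise ValueError("one region label per vertex required")
        present = set(self.region_labels[self.nose_mask])
        missing = set(NASAL_SUBUNITS) - present
        if missing:
            raise ValueError(f"nasal subunits missing from template: {sorted(missing)}")
        if not np.array_equal(self.nose_mask, self.region_labels != NON_NASAL):
            raise ValueError("nose_mask must equal the set of nasal-subunit vertices")


@dataclasses.dataclass
class PopulationModel:
    """Low-rank Gaussian shape-variation model.

    basis  : (K, N, 3) smooth per-vertex displacement fields, unit RMS
    scales : (K,) standard deviations in mm, positive and non-increasing
    """

    basis: np.ndarray
    scales: np.ndarray
    seed: int
    smoothness_bound: float = 1.0

    def __post_init__(self) -> None:
        self.basis = np.asarray(self.basis, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        if self.basis.ndim != 3 or self.basis.shape[2] != 3:
            raise ValueError("basis must have shape (K, N, 3)")
        if len(self.scales) != len(self.basis):
            raise ValueError("one scale per basis field required")
        if np.any(self.scales <= 0):
            raise ValueError("scales must be positive")
        if np.any(np.diff(self.scales) > 0):
            raise ValueError("scales must be non-increasing")

    @classmethod
    def build(
        cls,
        template: FaceTemplate,
        n_basis: int = 8,
        scales: np.ndarray | None = None,
        seed: int = 0,
        smoothing_steps: int = 60,
        smoothness_bound: float = 1.0,
    ) -> "PopulationModel":
        """Smooth random fields: white per-vertex noise diffused over the
        mesh graph (repeated neighborhood averaging), then normalized to
        unit RMS vertex displacement."""
        if scales is None:
            scales = np.linspace(3.0, 0.5, n_basis)
        mesh = template.mesh
        A = adjacency_matrix(mesh.n_vertices, mesh_edges(mesh.faces)) + sp.identity(
            mesh.n_vertices, format="csr"
        )
        A = sp.diags(1.0 / np.asarray(A.sum(axis=1)).ravel()) @ A
        rng = np.random.default_rng(seed)
        basis = np.empty((n_basis, mesh.n_vertices, 3))
        for k in range(n_basis):
            field = rng.standard_normal((mesh.n_vertices, 3))
            for _ in range(smoothing_steps):
                field = A @ field
            rms = np.sqrt(np.mean(np.sum(field**2, axis=1)))
            basis[k] = field / rms
        model = cls(basis, np.asarray(scales, dtype=float), seed, smoothness_bound)
        model.check_smoothness(mesh)
        return model

    def check_smoothness(self, mesh: StructuredMesh) -> float:
        """Max per-edge displacement difference across all fields; raises
        if it exceeds ``smoothness_bound`` (per unit RMS)."""
        e = mesh_edges(mesh.faces)
        diff = self.basis[:, e[:, 0]] - self.basis[:, e[:, 1]]
        worst = float(np.linalg.norm(diff, axis=2).max())
        if worst > self.smoothness_bound:
            raise ValueError(
                f"basis field edge difference {worst:.3f} exceeds bound "
                f"{self.smoothness_bound}"
            )
        return worst

    def mean_vertex_variance(self) -> float:
        """Mean over vertices of E||displacement||^2, in mm^2."""
        per_vertex = np.einsum("k,kni->n", self.scales**2, self.basis**2)
        return float(per_vertex.mean())


@dataclasses.dataclass
class DefectiveFace:
    """A face with the full nasal region deleted, plus its defect rim."""

    mesh: StructuredMesh
    defect_curve: BoundaryCurve
    source_id: str


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------


def _label_one(u: float, v: float) -> str:
    if abs(u) > _U_NOSE or v < _V_NOSE_BOT or v > _V_NOSE_TOP:
        return NON_NASAL
    side = "L" if u < 0 else "R"
    if abs(u) < 0.08:  # midline strip: dorsum / tip / columella
        if v >= 0.0:
            return "nasal_dorsum"
        if v >= -0.18:
            return "nasal_tip"
        return "nasal_columella"
    if v >= 0.05:
        return f"nasal_sidewall_{side}"
    if v >= -0.10:
        return f"soft_triangle_{side}"
    return f"nasal_ala_{side}"


def make_template(
    grid_resolution: int = 33,
    face_halfwidth: float = 70.0,
    face_halfheight: float = 90.0,
) -> FaceTemplate:
    """Deterministic analytic face template.

    A smooth convex dome with a protruding nose (sum of anisotropic
    Gaussian bumps for dorsum, tip, alae and columella) triangulated as a
    regular grid over (u, v) in [-1, 1]^2, closed at the back by a single
    apex vertex so the surface has no outer boundary.  Bilaterally
    symmetric; region labels come from the parametric zones of the bump
    construction.
    """
    if grid_resolution < 16:
        raise ValueError("grid_resolution must be >= 16")
    r = grid_resolution
    u1 = np.linspace(-1.0, 1.0, r)
    v1 = np.linspace(-1.0, 1.0, r)
    uu, vv = np.meshgrid(u1, v1, indexing="xy")
    u, v = uu.ravel(), vv.ravel()

    z = 42.0 * np.exp(-(u**2 / 1.1 + v**2 / 1.8))
    z += 9.0 * np.exp(-(u**2 / (2 * 0.055**2)) - ((v - 0.10) ** 2 / (2 * 0.14**2)))
    z += 13.0 * np.exp(-(u**2 / (2 * 0.075**2)) - ((v + 0.14) ** 2 / (2 * 0.075**2)))
    for s in (-1.0, 1.0):
        z += 6.5 * np.exp(
            -(((u - s * 0.115) ** 2) / (2 * 0.05**2)) - ((v + 0.16) ** 2 / (2 * 0.05**2))
        )
    z += 4.0 * np.exp(-(u**2 / (2 * 0.03**2)) - ((v + 0.225) ** 2 / (2 * 0.045**2)))

    verts = np.column_stack([face_halfwidth * u, face_halfheight * v, z])

    faces = []
    for j in range(r - 1):
        for i in range(r - 1):
            a = j * r + i
            b = a + 1
            c = a + r
            d = c + 1
            faces.append((a, b, d))  # CCW seen from +z (the viewer)
            faces.append((a, d, c))
    sheet = StructuredMesh(verts, np.array(faces, dtype=np.int64), topology_id="tmp-sheet")
    rim = boundary_loops(sheet)[0]

    apex = np.array([[0.0, 0.0, -55.0]])
    verts = np.vstack([verts, apex])
    apex_idx = len(verts) - 1
    cap = [(apex_idx, rim[(k + 1) % len(rim)], rim[k]) for k in range(len(rim))]
    all_faces = np.vstack([sheet.faces, np.array(cap, dtype=np.int64)])
    mesh = StructuredMesh(verts, all_faces, topology_id=f"synthface-r{grid_resolution}")

    labels = np.array([_label_one(ui, vi) for ui, vi in zip(u, v)] + [NON_NASAL], dtype=object)
    return FaceTemplate(mesh, labels, labels != NON_NASAL)


# ---------------------------------------------------------------------------
# population sampling and defect simulation
# ---------------------------------------------------------------------------


def sample_population(
    template: FaceTemplate,
    model: PopulationModel,
    n: int,
    seed: int | None = None,
    max_scale_fraction: float = 0.05,
) -> list:
    """Draw ``n`` faces: template + sum_k c_k basis_k, c_k ~ N(0, scales_k^2).

    All outputs share the template's topology_id.  ``seed`` defaults to
    the model's own seed; passing a different one yields an independent
    cohort from the same shape model (e.g. held-out evaluation cases).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    diag = template.mesh.bbox_diagonal()
    if np.any(model.scales > max_scale_fraction * diag):
        raise ValueError(
            f"largest scale {model.scales.max():.2f} mm exceeds "
            f"{max_scale_fraction:.0%} of the template bbox diagonal ({diag:.1f} mm)"
        )
    rng = np.random.default_rng(model.seed if seed is None else seed)
    coeff = rng.standard_normal((n, len(model.scales))) * model.scales
    fields = np.einsum("nk,kij->nij", coeff, model.basis)
    return [template.mesh.with_vertices(template.mesh.vertices + f) for f in fields]


def simulate_defect(face: StructuredMesh, template: FaceTemplate):
    """Create a full nasal defect: delete the nose region and its triangles.

    Returns ``(defective_face, nose_original)`` — the defective mesh with
    its ordered closed rim curve, and the deleted nasal submesh that
    serves as ground truth for evaluating a reconstruction.  Surviving
    vertex coordinates are untouched (deletion only).
    """
    if not face.same_topology(template.mesh):
        raise MeshTopologyError(
            f"face topology {face.topology_id!r} does not match template "
            f"{template.mesh.topology_id!r}"
        )
    defect_mesh, _ = submesh(face, ~template.nose_mask, tag="defect")
    nose_original, _ = submesh(face, template.nose_mask, tag="nose")
    curve = extract_boundary(defect_mesh)
    return (
        DefectiveFace(defect_mesh, curve, source_id=face.topology_id),
        nose_original,
    )


def apply_random_rigid(
    mesh: StructuredMesh,
    seed: int,
    max_angle_deg: float = 30.0,
    max_shift: float = 20.0,
):
    """Apply a random rotation (angle <= max_angle_deg about a uniform
    axis) and a random translation (each component uniform in
    [-max_shift, max_shift] mm).  Returns the transformed mesh and the
    ground-truth transform."""
    rng = np.random.default_rng(seed)
    if max_angle_deg > 0:
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        angle = np.radians(rng.uniform(0.0, max_angle_deg))
        w = axis * angle
    else:
        w = np.zeros(3)
    t = rng.uniform(-max_shift, max_shift, size=3) if max_shift > 0 else np.zeros(3)
    transform = RigidTransform(axis_angle_to_matrix(w), t)
    return mesh.with_vertices(transform.apply(mesh.vertices)), transform
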