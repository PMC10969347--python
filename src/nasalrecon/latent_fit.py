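"""Personalized target-reference-face construction by latent/rigid fitting.

After training, the encoder is discarded and the decoder acts as a face
generator.  Given a defective face S1, this module jointly optimizes the
latent code z and a rigid motion (R, T) of the generated face
S2 = decode(z) to minimize

    CD(S1, R S2 + T) + lambda (||z|| - 1)^2,

where CD is the *unidirectional* chamfer distance: the mean over S1 of
squared distances to nearest neighbors in S2.  Nearest-neighbor
correspondences are recomputed every iteration; the rotation is
parameterized by an axis-angle 3-vector (exponential map), so the
optimization is unconstrained and runs under adaptive-moment gradient
descent.  The resulting transformed decoded face is the personalized
target reference face from which missing nasal anatomy is copied.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from . import nn
from .autoencoder import ModelParams, reg_loss, reg_loss_grad
from .geometry import RigidTransform, axis_angle_to_matrix, rotation_matrix_derivatives
from .mesh_core import FaceGraph, StructuredMesh
from .synthetic_faces import DefectiveFace

__all__ = ["FitConfig", "FitResult", "chamfer_unidirectional", "fit_trf", "fit_rigid"]


@dataclasses.dataclass
class FitConfig:
    """Optimizer settings for target-reference-face fitting.

    lambda_reg reuses the training regularization weight (default 0.01).
    The learning rate halves whenever the objective has not improved for
    ``lr_patience`` iterations; convergence is declared after
    ``convergence_streak`` consecutive relative changes below
    ``convergence_tol``.
    """

    max_iters: int = 500
    learning_rate: float = 0.02
    lambda_reg: float = 0.01
    z_init_seed: int = 0
    convergence_tol: float = 1e-6
    restarts: int = 3
    optimize_z: bool = True
    optimize_rigid: bool = True
    lr_patience: int = 50
    lr_factor: float = 0.5
    convergence_streak: int = 20

    def __post_init__(self) -> None:
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclasses.dataclass
class FitResult:
    """Best fit over restarts: latent code, rigid motion, and the
    transformed decoded mesh (the target reference face)."""

    z_star: np.ndarray
    transform_star: RigidTransform
    trf: StructuredMesh
    objective_history: list
    converged: bool

    @property
    def final_objective(self) -> float:
        return float(min(self.objective_history))


def chamfer_unidirectional(s1: np.ndarray, s2: np.ndarray) -> float:
    """(1/|S1|) sum over x in S1 of min over y in S2 of ||x - y||^2, mm^2.

    Not symmetric: only S1 must be covered by S2.
    """
    s1 = np.asarray(s1, dtype=float).reshape(-1, 3)
    s2 = np.asarray(s2, dtype=float).reshape(-1, 3)
    if len(s1) == 0:
        raise ValueError("S1 (source point set) is empty")
    if len(s2) == 0:
        raise ValueError("S2 (target point set) is empty")
    d, _ = cKDTree(s2).query(s1)
    return float(np.mean(d**2))


def _source_points(defect) -> np.ndarray:
    if isinstance(defect, DefectiveFace):
        return defect.mesh.vertices
    if isinstance(defect, StructuredMesh):
        return defect.vertices
    return np.asarray(defect, dtype=float).reshape(-1, 3)


def _run_descent(
    s1: np.ndarray,
    decode_fn,
    z0: np.ndarray | None,
    y_fixed: np.ndarray | None,
    center: np.ndarray,
    t_init: np.ndarray,
    config: FitConfig,
):
    """Adam descent over (z, axis-angle w, translation).

    The rotation acts about ``center`` (a fixed point independent of z),
    which decouples rotation from translation and is converted back to
    the standard R p + T form at the end.  ``decode_fn(z) -> (Y, cache)``
    and ``decode_fn.backward(cache, dY) -> dz`` when z is optimized;
    otherwise ``y_fixed`` is the static generated point set.
    """
    lam = config.lambda_reg
    slots = {"w": np.zeros(3), "t": t_init.astype(float).copy()}
    if config.optimize_z:
        slots["z"] = np.asarray(z0, dtype=float).copy()
    adam = nn.Adam(slots, lr=config.learning_rate)
    adam.lr = config.learning_rate
    z = np.asarray(z0, dtype=float).copy() if z0 is not None else None

    history: list = []
    best = {"obj": np.inf, "w": slots["w"].copy(), "t": slots["t"].copy(),
            "z": None if z is None else z.copy()}
    streak = 0
    since_improve = 0
    converged = False
    n1 = len(s1)

    Y = cache = None
    if y_fixed is not None:
        Y = y_fixed
    for it in range(config.max_iters):
        if config.optimize_z:
            Y, cache = decode_fn(slots["z"])
            z = slots["z"]
        R = axis_angle_to_matrix(slots["w"])
        Yc = Y - center
        P2 = Yc @ R.T + center + slots["t"]
        _, idx = cKDTree(P2).query(s1)
        diff = P2[idx] - s1
        cd = float(np.mean(np.einsum("ij,ij->i", diff, diff)))
        obj = cd + (lam * reg_loss(z) if z is not None else 0.0)
        if not np.isfinite(obj):
            raise RuntimeError(f"non-finite objective at iteration {it}")
        history.append(obj)

        if obj < best["obj"] - 1e-15:
            best = {"obj": obj, "w": slots["w"].copy(), "t": slots["t"].copy(),
                    "z": None if z is None else z.copy()}
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.lr_patience:
                adam.lr *= config.lr_factor
                since_improve = 0
        if it > 0:
            rel = abs(history[-2] - obj) / max(abs(history[-2]), 1e-12)
            streak = streak + 1 if rel < config.convergence_tol else 0
            if streak >= config.convergence_streak:
                converged = True
                break

        g = (2.0 / n1) * diff  # d obj / d P2 rows (at matched indices)
        grads = {}
        dP2 = np.zeros_like(Y)
        np.add.at(dP2, idx, g)
        if config.optimize_rigid:
            grads["t"] = g.sum(axis=0)
            dR = dP2.T @ Yc
            dRdw = rotation_matrix_derivatives(slots["w"], R)
            grads["w"] = np.einsum("kij,ij->k", dRdw, dR)
        if config.optimize_z:
            dY = dP2 @ R
            dz = decode_fn.backward(cache, dY)
            grads["z"] = dz + lam * reg_loss_grad(slots["z"])
        adam.step(slots, grads)

    return best, history, converged


def fit_trf(
    defect,
    params: ModelParams,
    graph: FaceGraph,
    config: FitConfig | None = None,
    exclude_mask: np.ndarray | None = None,
    z_init: np.ndarray | None = None,
) -> FitResult:
    """Construct the personalized target reference face for a defect.

    ``defect`` may be a DefectiveFace, a StructuredMesh, or raw points;
    its vertices form S1 (all of them — no subsampling at the template
    resolutions used here).  z starts uniformly on the unit hypersphere
    (seeded; ``z_init`` overrides), R at identity, and T at the centroid
    offset between S1 and the decoded face restricted to vertices outside
    ``exclude_mask`` (the template nose mask, when known).  Returns the
    best restart.
    """
    config = config or FitConfig()
    s1 = _source_points(defect)
    if len(s1) == 0:
        raise ValueError("defect mesh is empty")
    ops = getattr(graph, "_nn_ops", None) or nn.GraphOps(graph)
    graph._nn_ops = ops
    mcfg, weights, ref = params.config, params.weights, params.ref_vertices
    center = ref.mean(axis=0)
    keep = ~np.asarray(exclude_mask, dtype=bool) if exclude_mask is not None else None

    class _Decoder:
        def __call__(self, z):
            out, cache = nn.decoder_forward(weights, ops, mcfg, z[None])
            return out[0] + ref, cache

        def backward(self, cache, dY):
            _, dZ = nn.decoder_backward(weights, ops, mcfg, cache, dY[None])
            return dZ[0]

    decode_fn = _Decoder()

    best_overall = None
    errors: list = []
    for r in range(config.restarts):
        rng = np.random.default_rng((config.z_init_seed + 7919 * r) % (2**31))
        if z_init is not None:
            z0 = np.asarray(z_init, dtype=float).copy()
        else:
            z0 = rng.standard_normal(mcfg.latent_dim)
            z0 /= np.linalg.norm(z0)
        Y0, _ = decode_fn(z0)
        ref_pts = Y0[keep] if keep is not None else Y0
        t0 = s1.mean(axis=0) - ref_pts.mean(axis=0)
        try:
            best, history, converged = _run_descent(
                s1, decode_fn, z0 if config.optimize_z else None,
                None if config.optimize_z else Y0,
                center, t0, config,
            )
            if config.optimize_z:
                z_star = best["z"]
            else:
                z_star = z0
        except RuntimeError as exc:
            errors.append(f"restart {r}: {exc}")
            continue
        if best_overall is None or best["obj"] < best_overall[0]["obj"]:
            best_overall = (best, history, converged, z_star)
    if best_overall is None:
        raise RuntimeError("all restarts failed: " + "; ".join(errors))

    best, history, converged, z_star = best_overall
    R = axis_angle_to_matrix(best["w"])
    T = center + best["t"] - R @ center  # back to the standard R p + T form
    transform = RigidTransform(R, T)
    Y_star, _ = decode_fn(z_star)
    trf = StructuredMesh(
        transform.apply(Y_star), params.template_faces, params.topology_id
    )
    return FitResult(z_star, transform, trf, history, converged)


def fit_rigid(
    defect,
    source_mesh: StructuredMesh,
    config: FitConfig | None = None,
    exclude_mask: np.ndarray | None = None,
):
    """Rigid-only alignment of a fixed mesh (e.g. the mean template) to a
    defect, under the same chamfer objective.  Returns (transform,
    transformed mesh, objective history, converged)."""
    config = dataclasses.replace(config or FitConfig(), optimize_z=False, restarts=1)
    s1 = _source_points(defect)
    Y = source_mesh.vertices
    center = Y.mean(axis=0)
    keep = ~np.asarray(exclude_mask, dtype=bool) if exclude_mask is not None else None
    ref_pts = Y[keep] if keep is not None else Y
    t0 = s1.mean(axis=0) - ref_pts.mean(axis=0)
    best, history, converged = _run_descent(s1, None, None, Y, center, t0, config)
    R = axis_angle_to_matrix(best["w"])
    T = center + best["t"] - R @ center
    transform = RigidTransform(R, T)
    aligned = source_mesh.with_vertices(transform.apply(Y))
    return transform, aligned, history, converged
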