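"""Rigid-body transforms and point-to-surface queries.

Rotations are represented internally as axis-angle 3-vectors mapped to
SO(3) by the exponential map, which keeps gradient-based optimization
unconstrained.  Closest-point queries against a triangle soup are exact
(point-to-triangle projection over every candidate triangle), evaluated
in chunks to bound memory.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import trimesh.triangles

__all__ = [
    "RigidTransform",
    "axis_angle_to_matrix",
    "rotation_matrix_derivatives",
    "rotation_angle_deg",
    "closest_points_on_mesh",
]

_EPS = 1e-12


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array(
        [
            [0.0, -v[2], v[1]],
            [v[2], 0.0, -v[0]],
            [-v[1], v[0], 0.0],
        ]
    )


def axis_angle_to_matrix(w: np.ndarray) -> np.ndarray:
    """Rodrigues exponential map from an axis-angle 3-vector to SO(3)."""
    w = np.asarray(w, dtype=float).reshape(3)
    theta = np.linalg.norm(w)
    if theta < 1e-10:
        # second-order expansion, exact enough at double precision
        K = _skew(w)
        return np.eye(3) + K + 0.5 * (K @ K)
    K = _skew(w / theta)
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def rotation_matrix_derivatives(w: np.ndarray, R: np.ndarray | None = None) -> np.ndarray:
    """Return dR/dw as an array of shape (3, 3, 3): [i] = dR/dw_i.

    Closed form for the derivative of the exponential map; at w = 0 the
    derivative reduces to the skew generators.
    """
    w = np.asarray(w, dtype=float).reshape(3)
    if R is None:
        R = axis_angle_to_matrix(w)
    theta2 = float(w @ w)
    out = np.empty((3, 3, 3))
    if theta2 < 1e-16:
        for i in range(3):
            e = np.zeros(3)
            e[i] = 1.0
            out[i] = _skew(e)
        return out
    ImR = np.eye(3) - R
    for i in range(3):
        e = np.zeros(3)
        e[i] = 1.0
        v = w[i] * w + np.cross(w, ImR @ e)
        out[i] = (_skew(v) @ R) / theta2
    return out


def rotation_angle_deg(R: np.ndarray) -> float:
    """Rotation angle of R in degrees (0..180)."""
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclasses.dataclass
class RigidTransform:
    """A proper rigid motion p -> R p + t (R in SO(3), t in mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-9:
            raise ValueError(f"rotation is not orthonormal (max |R'R - I| = {err:.2e})")
        det = np.linalg.det(self.rotation)
        if abs(det - 1.0) > 1e-9:
            raise ValueError(f"rotation determinant is {det:.9f}, expected +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, w: np.ndarray, translation: np.ndarray) -> "RigidTransform":
        return cls(axis_angle_to_matrix(w), translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


def closest_points_on_mesh(
    points: np.ndarray,
    vertices: np.ndarray,
    faces: np.ndarray,
    chunk_pairs: int = 1_000_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact closest point on a triangle mesh for each query point.

    Returns (closest_points (P,3), distances (P,), triangle_index (P,)).
    Ties are broken by the lowest triangle index.  Work is chunked over
    triangles so peak memory stays near ``chunk_pairs`` point-triangle
    pairs.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    tris = np.asarray(vertices, dtype=float)[np.asarray(faces, dtype=int)]
    P, T = len(points), len(tris)
    if P == 0:
        raise ValueError("no query points")
    if T == 0:
        raise ValueError("target mesh has no triangles")

    best_d2 = np.full(P, np.inf)
    best_pt = np.zeros((P, 3))
    best_tri = np.zeros(P, dtype=int)
    step = max(1, chunk_pairs // P)
    for t0 in range(0, T, step):
        sub = tris[t0 : t0 + step]
        C = len(sub)
        rep_tris = np.repeat(sub, P, axis=0)
        rep_pts = np.tile(points, (C, 1))
        cp = trimesh.triangles.closest_point(rep_tris, rep_pts).reshape(C, P, 3)
        d2 = np.einsum("cpk,cpk->cp", cp - points[None], cp - points[None])
        ci = np.argmin(d2, axis=0)
        cd2 = d2[ci, np.arange(P)]
        better = cd2 < best_d2
        best_d2[better] = cd2[better]
        best_pt[better] = cp[ci[better], np.flatnonzero(better)]
        best_tri[better] = t0 + ci[better]
    return best_pt, np.sqrt(best_d2), best_tri
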