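"""Deviation metrics: morphological similarity and edge fitness.

Morphological similarity compares a reconstructed nose against the
original nose as unsigned point-to-surface distances from each test
vertex to the reference mesh; the root-mean-square of those distances is
the *3D surface deviation* and their maximum the *max surface
deviation*, localized to one of the nine nasal subunits via the nearest
reference vertex.  Edge fitness compares the reconstructed nose's edge
curve against the defect rim: both closed curves are resampled uniformly
by arc length and each nose-edge sample is paired with its closest point
on the defect-edge polyline (continuous, not vertex-snapped), giving the
*curve deviation* (RMS) and *max curve deviation*.  Case series are
summarized as mean +/- sample standard deviation plus a subunit tally of
maximum-deviation locations.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import numpy as np

from .geometry import closest_points_on_mesh
from .mesh_core import BoundaryCurve, StructuredMesh
from scipy.spatial import cKDTree

__all__ = ["DeviationReport", "surface_deviation", "curve_deviation", "summarize"]


@dataclasses.dataclass
class DeviationReport:
    """Per-comparison deviation statistics, all distances in mm."""

    rmsd: float
    max_deviation: float
    max_location: np.ndarray  # 3-vector of the worst test point
    max_label: str  # nasal subunit, or "n/a" for curves
    per_point: np.ndarray

    def __post_init__(self) -> None:
        self.per_point = np.asarray(self.per_point, dtype=float)
        assert abs(self.rmsd - float(np.sqrt(np.mean(self.per_point**2)))) < 1e-9
        assert abs(self.max_deviation - float(self.per_point.max())) < 1e-12


def _report(per_point: np.ndarray, locations: np.ndarray, labels) -> DeviationReport:
    i = int(np.argmax(per_point))
    return DeviationReport(
        rmsd=float(np.sqrt(np.mean(per_point**2))),
        max_deviation=float(per_point[i]),
        max_location=np.asarray(locations[i], dtype=float),
        max_label=labels if isinstance(labels, str) else str(labels[i]),
        per_point=per_point,
    )


def surface_deviation(
    test: StructuredMesh,
    reference: StructuredMesh,
    subunits: np.ndarray | None = None,
) -> DeviationReport:
    """Unsigned point-to-surface distance from each ``test`` vertex to the
    ``reference`` mesh (closest point on any triangle).

    Deliberately asymmetric: the documented direction is reconstruction
    (test) against ground truth (reference).  ``subunits`` is an optional
    per-reference-vertex label array; the maximum deviation is then
    localized to the subunit of the reference vertex nearest the worst
    test point.
    """
    if test.n_vertices == 0 or reference.n_vertices == 0:
        raise ValueError("empty mesh")
    _, dist, _ = closest_points_on_mesh(test.vertices, reference.vertices, reference.faces)
    if subunits is not None:
        subunits = np.asarray(subunits, dtype=object)
        if len(subunits) != reference.n_vertices:
            raise ValueError("one subunit label per reference vertex required")
        worst = test.vertices[int(np.argmax(dist))]
        _, nearest_ref = cKDTree(reference.vertices).query(worst)
        label = str(subunits[nearest_ref])
    else:
        label = "n/a"
    return _report(dist, test.vertices, label)


def _resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Uniform arc-length resampling of a closed polyline to n points,
    starting at the polyline's first vertex."""
    pts = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    t = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 3))
    for c in range(3):
        out[:, c] = np.interp(t, s, pts[:, c])
    return out


def _point_to_polyline(points: np.ndarray, poly: np.ndarray, closed: bool) -> np.ndarray:
    """Min distance of each point to a polyline (closest point on any
    segment, continuous along segments)."""
    a = poly
    b = np.roll(poly, -1, axis=0) if closed else poly[1:]
    if not closed:
        a = poly[:-1]
    ab = b - a  # (S, 3)
    denom = np.einsum("sk,sk->s", ab, ab)
    denom[denom == 0] = 1.0
    ap = points[:, None, :] - a[None, :, :]  # (P, S, 3)
    t = np.clip(np.einsum("psk,sk->ps", ap, ab) / denom, 0.0, 1.0)
    closest = a[None] + t[:, :, None] * ab[None]
    d = np.linalg.norm(points[:, None, :] - closest, axis=2)
    return d.min(axis=1)


def curve_deviation(
    nose_edge: BoundaryCurve,
    defect_edge: BoundaryCurve,
    n_samples: int = 200,
) -> DeviationReport:
    """Edge fitness between the reconstructed nose's edge curve and the
    defect rim.

    Both closed curves are resampled to ``n_samples`` points by arc
    length; each resampled nose-edge point is paired with the closest
    point on the defect-edge polyline.  RMS and maximum of the pair
    distances form the curve deviation and max curve deviation.
    """
    if not nose_edge.closed or not defect_edge.closed:
        raise ValueError("curve deviation requires closed curves")
    if n_samples < 8:
        raise ValueError("n_samples must be >= 8")
    src = _resample_closed(nose_edge.points, n_samples)
    tgt = _resample_closed(defect_edge.points, n_samples)
    dist = _point_to_polyline(src, tgt, closed=True)
    return _report(dist, src, "n/a")


def summarize(reports: list) -> dict:
    """Mean and sample SD (n-1 denominator) of rmsd and max deviation,
    plus the tally of max-deviation subunit locations."""
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to summarize")
    rmsd = np.array([r.rmsd for r in reports])
    mx = np.array([r.max_deviation for r in reports])
    tally = Counter(r.max_label for r in reports if r.max_label != "n/a")
    return {
        "n": len(reports),
        "rmsd_mean": float(rmsd.mean()),
        "rmsd_sd": float(rmsd.std(ddof=1)),
        "max_mean": float(mx.mean()),
        "max_sd": float(mx.std(ddof=1)),
        "subunit_tally": dict(sorted(tally.items())),
    }
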