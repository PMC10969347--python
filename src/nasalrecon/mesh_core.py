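"""Fixed-topology triangle meshes, OBJ I/O, and the face-graph hierarchy.

A *structured* mesh is one that shares a template topology: two meshes
with equal ``topology_id`` have identical vertex counts and face arrays,
so equal vertex indices denote equal anatomical locations across
individuals.  This module also builds the multi-level graph (normalized
adjacency operators plus vertex-clustering pool maps) consumed by the
graph-convolutional autoencoder, extracts ordered boundary loops, and
selects mesh regions enclosed by a curve.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree

__all__ = [
    "MeshFormatError",
    "MeshTopologyError",
    "RegionSelectionError",
    "StructuredMesh",
    "BoundaryCurve",
    "FaceGraph",
    "read_obj",
    "write_obj",
    "write_curve_xyz",
    "read_curve_xyz",
    "mesh_edges",
    "adjacency_matrix",
    "normalize_adjacency",
    "build_face_graph",
    "boundary_loops",
    "extract_boundary",
    "select_region",
    "submesh",
]


class MeshFormatError(ValueError):
    """Malformed mesh file or mesh arrays."""


class MeshTopologyError(ValueError):
    """Mesh connectivity violates an operation's precondition."""


class RegionSelectionError(ValueError):
    """A cutting curve failed to separate the mesh."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class StructuredMesh:
    """Triangle mesh with vertex-wise anatomical correspondence.

    vertices : (N, 3) float64, coordinates in mm
    faces    : (M, 3) int, 0-based vertex indices, consistently oriented
    topology_id : opaque tag; equal tags imply identical N, M and faces
    """

    vertices: np.ndarray
    faces: np.ndarray
    topology_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must have shape (N, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshFormatError("faces must have shape (M, 3)")
        if len(self.vertices) == 0 or len(self.faces) == 0:
            raise MeshFormatError("vertex and face counts must be positive")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise MeshFormatError("face index out of range")
        f = self.faces
        if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
            raise MeshFormatError("degenerate triangle (repeated vertex index)")
        if not self.topology_id:
            self.topology_id = "obj:" + hashlib.sha1(self.faces.tobytes()).hexdigest()[:12]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def same_topology(self, other: "StructuredMesh") -> bool:
        return (
            self.topology_id == other.topology_id
            and self.n_vertices == other.n_vertices
            and np.array_equal(self.faces, other.faces)
        )

    def with_vertices(self, vertices: np.ndarray) -> "StructuredMesh":
        """Same topology, new coordinates."""
        return StructuredMesh(np.asarray(vertices, dtype=float), self.faces, self.topology_id)

    def bbox_diagonal(self) -> float:
        return float(np.linalg.norm(self.vertices.max(0) - self.vertices.min(0)))


@dataclasses.dataclass
class BoundaryCurve:
    """Ordered polyline in mm; when closed, the last point connects to the first."""

    points: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise MeshFormatError("curve points must have shape (P, 3)")
        if self.closed and len(self.points) < 3:
            raise MeshFormatError("a closed curve needs at least 3 points")
        seg = np.diff(self.points, axis=0)
        if len(seg) and np.any(np.linalg.norm(seg, axis=1) == 0.0):
            raise MeshFormatError("consecutive curve points must be distinct")

    def __len__(self) -> int:
        return len(self.points)


@dataclasses.dataclass
class FaceGraph:
    """Multi-level graph hierarchy for graph convolutions.

    level_adjacency : per-level normalized vertex-adjacency operators
                      (symmetric, rows summing to 1)
    pool_maps       : pool_maps[l][i] = coarse index at level l+1 of fine
                      vertex i at level l (surjective, covers every vertex)
    level_positions : per-level vertex coordinates (cluster centroids)
    """

    level_adjacency: list
    pool_maps: list
    n_levels: int
    level_positions: list

    @property
    def level_sizes(self) -> list:
        return [a.shape[0] for a in self.level_adjacency]


# ---------------------------------------------------------------------------
# OBJ and curve I/O
# ---------------------------------------------------------------------------


def read_obj(path) -> StructuredMesh:
    """Read a Wavefront OBJ triangle mesh.

    Only ``v`` and ``f`` records are used; texture/normal indices and
    other records are ignored.  Polygonal faces are fan-triangulated.
    1-based (or negative, relative) OBJ indices become 0-based.
    """
    vertices: list = []
    faces: list = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if tokens[0] == "v":
            if len(tokens) < 4:
                raise MeshFormatError(f"{path}:{lineno}: vertex record needs 3 coordinates")
            try:
                vertices.append([float(t) for t in tokens[1:4]])
            except ValueError as exc:
                raise MeshFormatError(f"{path}:{lineno}: bad vertex coordinate") from exc
        elif tokens[0] == "f":
            idx = []
            for tok in tokens[1:]:
                head = tok.split("/")[0]
                try:
                    i = int(head)
                except ValueError as exc:
                    raise MeshFormatError(f"{path}:{lineno}: bad face index {tok!r}") from exc
                if i == 0:
                    raise MeshFormatError(f"{path}:{lineno}: OBJ indices are 1-based, got 0")
                idx.append(i - 1 if i > 0 else len(vertices) + i)
            if len(idx) < 3:
                raise MeshFormatError(f"{path}:{lineno}: face with fewer than 3 vertices")
            for k in range(1, len(idx) - 1):  # fan triangulation
                tri = (idx[0], idx[k], idx[k + 1])
                if len(set(tri)) != 3:
                    raise MeshFormatError(f"{path}:{lineno}: non-triangulatable polygon face")
                faces.append(tri)
    if not vertices or not faces:
        raise MeshFormatError(f"{path}: no 'v'/'f' records found")
    return StructuredMesh(np.array(vertices, dtype=float), np.array(faces, dtype=np.int64))


def write_obj(path, mesh: StructuredMesh, precision: int = 8) -> None:
    """Write ``v``/``f`` records; coordinates keep ``precision`` decimals."""
    fmt = f"v {{:.{precision}f}} {{:.{precision}f}} {{:.{precision}f}}\n"
    with open(path, "w") as fh:
        fh.write(f"# nasalrecon OBJ, {mesh.n_vertices} vertices, {mesh.n_faces} faces\n")
        for v in mesh.vertices:
            fh.write(fmt.format(*v))
        for f in mesh.faces + 1:
            fh.write(f"f {f[0]} {f[1]} {f[2]}\n")


def write_curve_xyz(path, curve: BoundaryCurve, precision: int = 8) -> None:
    """One ``x y z`` point per line, in curve order."""
    fmt = f"{{:.{precision}f}} {{:.{precision}f}} {{:.{precision}f}}\n"
    with open(path, "w") as fh:
        for p in curve.points:
            fh.write(fmt.format(*p))


def read_curve_xyz(path, closed: bool = True) -> BoundaryCurve:
    pts = np.loadtxt(path, dtype=float, ndmin=2)
    return BoundaryCurve(pts[:, :3], closed=closed)


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------


def mesh_edges(faces: np.ndarray) -> np.ndarray:
    """Unique undirected edges (E, 2) with u < v."""
    f = np.asarray(faces)
    e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0)


def adjacency_matrix(n: int, edges: np.ndarray) -> sp.csr_matrix:
    data = np.ones(len(edges))
    A = sp.coo_matrix((data, (edges[:, 0], edges[:, 1])), shape=(n, n))
    A = A + A.T
    A.data[:] = 1.0
    return A.tocsr()


def normalize_adjacency(A: sp.spmatrix, tol: float = 1e-13, max_iter: int = 500) -> sp.csr_matrix:
    """Self-loops plus iterated symmetric degree normalization.

    Repeating D^{-1/2} (A + I) D^{-1/2} until row sums converge yields a
    symmetric operator whose rows sum to 1 (a symmetric doubly-stochastic
    smoothing operator), so a constant per-vertex signal is preserved
    exactly — the property graph convolutions rely on here.
    """
    A = sp.csr_matrix(A, dtype=float) + sp.identity(A.shape[0], format="csr")
    for _ in range(max_iter):
        s = np.asarray(A.sum(axis=1)).ravel()
        if np.any(s <= 0):
            raise MeshTopologyError("vertex with no neighbors after self-loop addition")
        if np.abs(s - 1.0).max() < tol:
            break
        d = sp.diags(1.0 / np.sqrt(s))
        A = d @ A @ d
    return sp.csr_matrix(A)


def _vertex_quadrics(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Per-vertex 4x4 plane quadrics (sum of outer products of face planes)."""
    n = len(vertices)
    Q = np.zeros((n, 4, 4))
    if len(faces) == 0:
        return Q
    tri = vertices[faces]
    nrm = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    lens = np.linalg.norm(nrm, axis=1)
    ok = lens > 1e-12
    nrm[ok] /= lens[ok, None]
    d = -np.einsum("fk,fk->f", nrm, tri[:, 0])
    p = np.concatenate([nrm, d[:, None]], axis=1)  # (F, 4)
    K = np.einsum("fi,fj->fij", p, p)
    for c in range(3):
        np.add.at(Q, faces[:, c], K)
    return Q


def _coarsen_level(vertices: np.ndarray, faces: np.ndarray):
    """One level of vertex clustering by greedy quadric-ordered edge contraction.

    Edges are ranked by the quadric error of their midpoint; a maximal
    matching in that order merges vertex pairs (unmatched vertices stay as
    singletons), giving roughly a 2x reduction per level.  Returns
    (assignment, coarse_vertices, coarse_faces, coarse_edges).
    """
    n = len(vertices)
    edges = mesh_edges(faces)
    if len(edges) == 0:
        raise MeshTopologyError("cannot coarsen a graph with no edges")
    Q = _vertex_quadrics(vertices, faces)
    mid = 0.5 * (vertices[edges[:, 0]] + vertices[edges[:, 1]])
    mh = np.concatenate([mid, np.ones((len(mid), 1))], axis=1)
    Qe = Q[edges[:, 0]] + Q[edges[:, 1]]
    cost = np.einsum("ei,eij,ej->e", mh, Qe, mh)
    if not np.any(cost > 1e-12):  # degenerate/faceless graph: order by length
        cost = np.linalg.norm(vertices[edges[:, 0]] - vertices[edges[:, 1]], axis=1)

    order = np.argsort(cost, kind="stable")
    assign = np.full(n, -1, dtype=np.int64)
    nxt = 0
    for u, v in edges[order]:
        if assign[u] < 0 and assign[v] < 0:
            assign[u] = assign[v] = nxt
            nxt += 1
    for u in range(n):
        if assign[u] < 0:
            assign[u] = nxt
            nxt += 1

    coarse_vertices = np.zeros((nxt, 3))
    counts = np.bincount(assign, minlength=nxt).astype(float)
    for c in range(3):
        coarse_vertices[:, c] = np.bincount(assign, weights=vertices[:, c], minlength=nxt)
    coarse_vertices /= counts[:, None]

    cf = assign[faces]
    keep = (cf[:, 0] != cf[:, 1]) & (cf[:, 1] != cf[:, 2]) & (cf[:, 0] != cf[:, 2])
    cf = cf[keep]
    if len(cf):
        key = np.sort(cf, axis=1)
        _, first = np.unique(key, axis=0, return_index=True)
        cf = cf[np.sort(first)]
    ce = assign[edges]
    ce = ce[ce[:, 0] != ce[:, 1]]
    ce = np.unique(np.sort(ce, axis=1), axis=0)
    return assign, coarse_vertices, cf, ce


def build_face_graph(mesh: StructuredMesh, n_levels: int = 4) -> FaceGraph:
    """Build the pooling hierarchy: ``n_levels`` adjacency operators and
    ``n_levels - 1`` pool maps.  Level 0 matches the mesh; vertex counts
    strictly decrease with level."""
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    n = mesh.n_vertices
    referenced = np.zeros(n, dtype=bool)
    referenced[mesh.faces.ravel()] = True
    if not referenced.all():
        raise MeshTopologyError(
            f"mesh has {int((~referenced).sum())} isolated vertices (not in any face)"
        )
    edges = mesh_edges(mesh.faces)
    A = adjacency_matrix(n, edges)
    n_comp, _ = connected_components(A, directed=False)
    if n_comp != 1:
        raise MeshTopologyError(f"mesh is not connected ({n_comp} components)")

    adjacency = [normalize_adjacency(A)]
    positions = [mesh.vertices.copy()]
    pool_maps: list = []
    verts, faces = mesh.vertices, mesh.faces
    for _ in range(n_levels - 1):
        assign, verts, faces, ce = _coarsen_level(verts, faces)
        if len(verts) < 4:
            raise MeshTopologyError(
                f"coarsening would produce {len(verts)} vertices (< 4); reduce n_levels"
            )
        pool_maps.append(assign)
        positions.append(verts)
        adjacency.append(normalize_adjacency(adjacency_matrix(len(verts), ce)))
    return FaceGraph(adjacency, pool_maps, n_levels, positions)


# ---------------------------------------------------------------------------
# boundary loops and region selection
# ---------------------------------------------------------------------------


def boundary_loops(mesh: StructuredMesh) -> list:
    """Ordered vertex-index loops of boundary edges (edges in one triangle).

    Loops follow the direction the boundary edges carry in their unique
    incident face, i.e. counterclockwise with respect to outward normals
    for a consistently oriented mesh.
    """
    f = mesh.faces
    directed = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    und = np.sort(directed, axis=1)
    _, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    boundary = directed[counts[inv] == 1]
    succ: dict = {}
    for u, v in boundary:
        if u in succ:
            raise MeshTopologyError(f"non-manifold boundary at vertex {u}")
        succ[int(u)] = int(v)
    loops = []
    seen: set = set()
    for start in sorted(succ):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = succ[start]
        while cur != start:
            loop.append(cur)
            seen.add(cur)
            cur = succ.get(cur)
            if cur is None:
                raise MeshTopologyError("open boundary chain (mesh edge structure broken)")
        loops.append(np.array(loop, dtype=np.int64))
    return loops


def extract_boundary(mesh: StructuredMesh, select: str | None = None) -> BoundaryCurve:
    """The single ordered, closed boundary loop of ``mesh`` as a polyline.

    Errors if the mesh has no boundary or several loops; pass
    ``select="longest"`` to explicitly pick the longest of several.
    """
    loops = boundary_loops(mesh)
    if len(loops) == 0:
        raise MeshTopologyError("no boundary loop (mesh is closed); found 0 loops")
    if len(loops) > 1 and select != "longest":
        raise MeshTopologyError(
            f"found {len(loops)} boundary loops; pass select='longest' to pick one"
        )
    loop = max(loops, key=len) if len(loops) > 1 else loops[0]
    return BoundaryCurve(mesh.vertices[loop], closed=True)


def _curve_vertex_cycle(mesh: StructuredMesh, curve: BoundaryCurve) -> np.ndarray:
    """Indices of the closed vertex path tracing ``curve`` on the mesh graph.

    Each curve point maps to its nearest mesh vertex; consecutive anchors
    are joined by shortest (Euclidean-weighted) graph paths.
    """
    tree = cKDTree(mesh.vertices)
    _, anchors = tree.query(curve.points)
    keep = [anchors[0]]
    for a in anchors[1:]:
        if a != keep[-1]:
            keep.append(a)
    if curve.closed and len(keep) > 1 and keep[-1] == keep[0]:
        keep.pop()
    anchors = np.array(keep, dtype=np.int64)
    if len(anchors) < 3:
        raise RegionSelectionError("curve maps to fewer than 3 distinct mesh vertices")

    edges = mesh_edges(mesh.faces)
    w = np.linalg.norm(mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1)
    G = sp.coo_matrix(
        (w, (edges[:, 0], edges[:, 1])), shape=(mesh.n_vertices, mesh.n_vertices)
    ).tocsr()
    path: list = []
    n_anchor = len(anchors)
    for i in range(n_anchor):
        a, b = int(anchors[i]), int(anchors[(i + 1) % n_anchor])
        path.append(a)
        if b == a:
            continue
        # direct edge?
        row = G.indices[G.indptr[a] : G.indptr[a + 1]]
        col = G.indices[G.indptr[b] : G.indptr[b + 1]]
        if b in row or a in col:
            continue
        _, pred = dijkstra(G, directed=False, indices=a, return_predecessors=True)
        chain = []
        cur = b
        while cur != a and cur >= 0:
            chain.append(cur)
            cur = pred[cur]
        if cur < 0:
            raise RegionSelectionError("curve anchors are not connected on the mesh")
        path.extend(reversed(chain[1:]))  # interior vertices of the path
    # dedupe while preserving set semantics (cycle membership is what matters)
    return np.unique(np.array(path, dtype=np.int64))


def select_region(
    mesh: StructuredMesh,
    curve: BoundaryCurve,
    exterior_anchor: int | None = None,
    return_path: bool = False,
):
    """Boolean mask of vertices enclosed by a closed curve on the mesh.

    The curve's nearest-vertex cycle is removed from the vertex graph; the
    region returned is the union of remaining components that do NOT
    contain the exterior anchor (by default the vertex farthest from the
    curve).  Deterministic for fixed inputs.
    """
    if not curve.closed:
        raise RegionSelectionError("region selection needs a closed curve")
    cycle = _curve_vertex_cycle(mesh, curve)
    on_cycle = np.zeros(mesh.n_vertices, dtype=bool)
    on_cycle[cycle] = True

    edges = mesh_edges(mesh.faces)
    keep = ~on_cycle[edges[:, 0]] & ~on_cycle[edges[:, 1]]
    edges = edges[keep]
    A = sp.coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])),
        shape=(mesh.n_vertices, mesh.n_vertices),
    )
    n_comp, labels = connected_components(A + A.T, directed=False)
    labels = labels.copy()
    labels[on_cycle] = -1
    open_labels = np.unique(labels[labels >= 0])
    if len(open_labels) < 2:
        raise RegionSelectionError("curve does not separate the mesh into >= 2 components")

    if exterior_anchor is None:
        tree = cKDTree(curve.points)
        d, _ = tree.query(mesh.vertices)
        d[on_cycle] = -np.inf
        exterior_anchor = int(np.argmax(d))
    elif on_cycle[exterior_anchor]:
        raise RegionSelectionError("exterior anchor lies on the cutting path")
    anchor_label = labels[exterior_anchor]
    mask = (labels >= 0) & (labels != anchor_label)
    if return_path:
        return mask, cycle
    return mask


def submesh(mesh: StructuredMesh, vertex_mask: np.ndarray, tag: str = "sub"):
    """Submesh of faces whose three vertices are all inside ``vertex_mask``.

    Returns (mesh, old_to_new index map with -1 outside).  The new
    topology_id is derived from the parent's and the kept vertex set.
    """
    vertex_mask = np.asarray(vertex_mask, dtype=bool)
    idx_map = np.full(mesh.n_vertices, -1, dtype=np.int64)
    idx_map[vertex_mask] = np.arange(int(vertex_mask.sum()))
    keep_f = vertex_mask[mesh.faces].all(axis=1)
    if not keep_f.any():
        raise MeshTopologyError("vertex mask keeps no complete triangle")
    h = hashlib.sha1(np.flatnonzero(vertex_mask).tobytes()).hexdigest()[:8]
    new = StructuredMesh(
        mesh.vertices[vertex_mask],
        idx_map[mesh.faces[keep_f]],
        topology_id=f"{mesh.topology_id}/{tag}-{h}",
    )
    return new, idx_map
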