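"""Mesh data model, OBJ I/O, graph hierarchy, boundaries, region cuts."""

import numpy as np
import pytest

import nasalrecon as nr
from nasalrecon.mesh_core import (
    MeshFormatError,
    MeshTopologyError,
    RegionSelectionError,
    boundary_loops,
    mesh_edges,
    normalize_adjacency,
    adjacency_matrix,
)

from conftest import disk_mesh, grid_mesh, tetrahedron


class TestOBJ:
    def test_one_based_indices(self, tmp_path):
        p = tmp_path / "t.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 3\n")
        m = nr.read_obj(p)
        assert m.n_vertices == 3 and m.n_faces == 1
        assert np.array_equal(m.faces, [[0, 1, 2]])

    def test_texture_normal_indices_ignored(self, tmp_path):
        plain = tmp_path / "a.obj"
        slashed = tmp_path / "b.obj"
        plain.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 3\n")
        slashed.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nvt 0 0\nvn 0 0 1\nf 1/1/1 2/1/1 3/1/1\n")
        a, b = nr.read_obj(plain), nr.read_obj(slashed)
        assert np.array_equal(a.faces, b.faces)
        assert np.allclose(a.vertices, b.vertices)

    def test_quad_fan_triangulation(self, tmp_path):
        p = tmp_path / "q.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 1 1 0\nv 0 1 0\nf 1 2 3 4\n")
        m = nr.read_obj(p)
        assert m.n_faces == 2
        assert np.array_equal(m.faces, [[0, 1, 2], [0, 2, 3]])

    def test_roundtrip_identity(self, tmp_path, template):
        p = tmp_path / "face.obj"
        nr.write_obj(p, template.mesh)
        again = nr.read_obj(p)
        assert np.array_equal(again.faces, template.mesh.faces)
        assert np.allclose(again.vertices, template.mesh.vertices, atol=1e-6)

    @pytest.mark.parametrize(
        "text",
        [
            "v 0 0\nf 1 2 3\n",  # short vertex
            "v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2\n",  # short face
            "v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 x\n",  # bad index
            "v 0 0 0\nv 1 0 0\nv 0 1 0\nf 0 1 2\n",  # 0 index in 1-based format
        ],
    )
    def test_malformed_records_raise(self, tmp_path, text):
        p = tmp_path / "bad.obj"
        p.write_text(text)
        with pytest.raises(MeshFormatError):
            nr.read_obj(p)

    def test_degenerate_triangle_rejected(self):
        with pytest.raises(MeshFormatError):
            nr.StructuredMesh(np.zeros((3, 3)) + np.eye(3), [[0, 1, 1]])


class TestGraph:
    def test_single_triangle_fully_connected(self):
        m = nr.StructuredMesh(np.eye(3), [[0, 1, 2]])
        g = nr.build_face_graph(m, n_levels=1)
        A = g.level_adjacency[0].toarray()
        assert A.shape == (3, 3)
        assert (A > 0).all()

    def test_level_sizes_strictly_decrease(self, template):
        g = nr.build_face_graph(template.mesh, n_levels=4)
        sizes = g.level_sizes
        assert sizes[0] == template.mesh.n_vertices
        assert all(a > b for a, b in zip(sizes, sizes[1:]))

    def test_pool_maps_cover_every_fine_vertex(self, graph):
        for lvl, assign in enumerate(graph.pool_maps):
            assert len(assign) == graph.level_sizes[lvl]
            assert set(assign) == set(range(graph.level_sizes[lvl + 1]))

    def test_adjacency_rows_sum_to_one_and_symmetric(self, graph):
        for A in graph.level_adjacency:
            s = np.asarray(A.sum(axis=1)).ravel()
            assert np.abs(s - 1.0).max() < 1e-9
            assert abs(A - A.T).max() < 1e-12

    def test_constant_signal_preserved(self, graph):
        for A in graph.level_adjacency:
            c = np.full(A.shape[0], 3.7)
            assert np.abs(A @ c - 3.7).max() < 1e-9

    def test_isolated_vertex_rejected(self):
        verts = np.vstack([np.eye(3), [5.0, 5.0, 5.0]])
        m = nr.StructuredMesh(verts, [[0, 1, 2]])
        with pytest.raises(MeshTopologyError, match="isolated"):
            nr.build_face_graph(m, n_levels=1)

    def test_overdeep_coarsening_rejected(self):
        with pytest.raises(MeshTopologyError, match="< 4"):
            nr.build_face_graph(disk_mesh(6), n_levels=4)


class TestBoundary:
    def test_closed_mesh_has_no_boundary(self):
        with pytest.raises(MeshTopologyError, match="0 loops|no boundary"):
            nr.extract_boundary(tetrahedron())

    def test_disk_boundary_is_rim(self):
        n_rim = 17
        curve = nr.extract_boundary(disk_mesh(n_rim))
        assert curve.closed
        assert len(curve) == n_rim
        # counterclockwise w.r.t. the +z outward normal
        cross = np.cross(curve.points[0], curve.points[1])
        assert cross[2] > 0

    def test_boundary_length_matches_edge_incidence_oracle(self, template, population):
        defect, _ = nr.simulate_defect(population[0], template)
        mesh = defect.mesh
        # oracle: count undirected edges that belong to exactly one triangle
        f = mesh.faces
        e = np.sort(
            np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1
        )
        _, counts = np.unique(e, axis=0, return_counts=True)
        n_boundary_edges = int((counts == 1).sum())
        assert len(defect.defect_curve) == n_boundary_edges  # closed loop: #edges == #vertices

    def test_multiple_loops_need_explicit_flag(self):
        g = grid_mesh(7, 7)
        # cut an interior hole by dropping the faces around one vertex
        centre = 3 * 7 + 3
        keep = ~(g.faces == centre).any(axis=1)
        holed = nr.StructuredMesh(g.vertices, g.faces[keep])
        with pytest.raises(MeshTopologyError, match="2 boundary loops"):
            nr.extract_boundary(holed)
        longest = nr.extract_boundary(holed, select="longest")
        assert len(longest) == 24  # the outer rim of the 7x7 sheet


class TestSelectRegion:
    def test_star_of_one_vertex(self):
        g = grid_mesh(7, 7)
        centre = 3 * 7 + 3
        ring = [centre - 8, centre - 7, centre - 6, centre - 1, centre + 1,
                centre + 6, centre + 7, centre + 8]
        # close the ring in traversal order around the centre
        order = [centre - 8, centre - 7, centre - 6, centre + 1, centre + 8,
                 centre + 7, centre + 6, centre - 1]
        curve = nr.BoundaryCurve(g.vertices[order], closed=True)
        mask = nr.select_region(g, curve)
        assert mask.sum() == 1 and mask[centre]

    def test_nose_region_equals_template_labels(self, template, population):
        defect, _ = nr.simulate_defect(population[2], template)
        mask = nr.select_region(population[2], defect.defect_curve)
        assert np.array_equal(mask, template.nose_mask)

    def test_partition_with_swapped_anchor(self, template):
        mesh = template.mesh
        defect, _ = nr.simulate_defect(mesh, template)
        mask, path = nr.select_region(mesh, defect.defect_curve, return_path=True)
        inside_anchor = int(np.flatnonzero(mask)[0])
        complement = nr.select_region(mesh, defect.defect_curve, exterior_anchor=inside_anchor)
        path_mask = np.zeros(mesh.n_vertices, dtype=bool)
        path_mask[path] = True
        assert not (mask & complement).any()
        assert not (mask & path_mask).any()
        assert not (complement & path_mask).any()
        assert (mask | complement | path_mask).all()

    def test_non_separating_curve_raises(self):
        g = grid_mesh(6, 6)
        curve = nr.BoundaryCurve(g.vertices[[0, 1, 2]], closed=True)
        with pytest.raises(RegionSelectionError):
            nr.select_region(g, curve)


def test_normalize_adjacency_requires_neighbors():
    A = adjacency_matrix(3, np.array([[0, 1]]))
    # vertex 2 has only its self-loop; still normalizable
    out = normalize_adjacency(A)
    assert np.abs(np.asarray(out.sum(axis=1)).ravel() - 1).max() < 1e-9


def test_mesh_edges_unique_and_sorted(template):
    e = mesh_edges(template.mesh.faces)
    assert (e[:, 0] < e[:, 1]).all()
    assert len(np.unique(e, axis=0)) == len(e)
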