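"""Transformation graphs: path resolution, composition, field application."""

import numpy as np
import pytest

import structatlas as sa
from structatlas.errors import NotComposable, NotFound, OutOfField, Unreachable


def rigidish(rng, scale=1.0):
    m = np.eye(4)
    m[:3, :3] = np.linalg.qr(rng.normal(size=(3, 3)))[0] * scale
    m[:3, 3] = rng.normal(size=3) * 10
    return m


def affine_field(matrix, geometry):
    """Deformation field whose value at every voxel is the affine image of
    that voxel's world position (trilinear sampling is exact on it)."""
    grid = np.stack(
        np.meshgrid(*(np.arange(s) for s in geometry.shape), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    world = geometry.voxel_to_world_coords(grid)
    mapped = world @ matrix[:3, :3].T + matrix[:3, 3]
    return mapped.reshape(*geometry.shape, 3)


class TestResolvePath:
    def test_identity(self):
        tg = sa.TransformationGraph()
        tg.add_referential("A")
        assert tg.resolve_path("A", "A") == []

    def test_single_affine_reversed(self):
        tg = sa.TransformationGraph()
        t = tg.add_affine(sa.AffineTransform("A", "B", np.eye(4)))
        path = tg.resolve_path("B", "A")
        assert path == [(t, "inverse")]

    def test_prefers_two_hop_over_three_hop(self):
        rng = np.random.default_rng(0)
        tg = sa.TransformationGraph()
        # 2-hop route A-B-E and 3-hop route A-C-D-E
        for s, t in [("A", "B"), ("B", "E"), ("A", "C"), ("C", "D"), ("D", "E")]:
            tg.add_affine(sa.AffineTransform(s, t, rigidish(rng)))
        path = tg.resolve_path("A", "E")
        assert len(path) == 2
        assert path[0][0].target == "B"

    def test_unknown_referential(self):
        tg = sa.TransformationGraph()
        tg.add_referential("A")
        with pytest.raises(NotFound):
            tg.resolve_path("A", "ghost")

    def test_disconnected_is_none(self):
        tg = sa.TransformationGraph()
        tg.add_referential("A")
        tg.add_referential("B")
        assert tg.resolve_path("A", "B") is None

    def test_field_edges_are_directed(self, geom64):
        tg = sa.TransformationGraph()
        tg.add_field(
            sa.DeformationFieldTransform("A", "B", affine_field(np.eye(4), geom64), geom64)
        )
        assert tg.resolve_path("A", "B") is not None
        assert tg.resolve_path("B", "A") is None


class TestComposeAffinePath:
    def test_empty_path_is_identity(self):
        np.testing.assert_array_equal(
            sa.TransformationGraph.compose_affine_path([]), np.eye(4)
        )

    def test_inverse_pair_cancels(self):
        rng = np.random.default_rng(1)
        t = sa.AffineTransform("A", "B", rigidish(rng))
        composed = sa.TransformationGraph.compose_affine_path(
            [(t, "forward"), (t, "inverse")]
        )
        np.testing.assert_allclose(composed, np.eye(4), atol=1e-9)

    def test_matches_naive_triple_loop_product(self):
        rng = np.random.default_rng(2)
        mats = [rigidish(rng) for _ in range(3)]
        path = [
            (sa.AffineTransform(f"R{i}", f"R{i+1}", m), "forward")
            for i, m in enumerate(mats)
        ]
        composed = sa.TransformationGraph.compose_affine_path(path)

        def matmul(a, b):  # oracle: naive triple loop
            out = [[0.0] * 4 for _ in range(4)]
            for i in range(4):
                for j in range(4):
                    for k in range(4):
                        out[i][j] += a[i][k] * b[k][j]
            return np.array(out)

        expected = matmul(mats[2], matmul(mats[1], mats[0]))
        np.testing.assert_allclose(composed, expected, atol=1e-9)

    def test_field_step_not_composable(self, geom64):
        t = sa.DeformationFieldTransform("A", "B", affine_field(np.eye(4), geom64), geom64)
        with pytest.raises(NotComposable):
            sa.TransformationGraph.compose_affine_path([(t, "forward")])


class TestMapPoint:
    def test_identity_path(self):
        tg = sa.TransformationGraph()
        tg.add_referential("A")
        np.testing.assert_array_equal(tg.map_point([1, 2, 3], "A", "A"), [1, 2, 3])

    def test_zero_displacement_field_is_identity(self):
        geom = sa.VolumeGeometry((10, 10, 10), (2, 2, 2))
        tg = sa.TransformationGraph()
        tg.add_field(sa.DeformationFieldTransform("A", "B", affine_field(np.eye(4), geom), geom))
        pt = np.array([5.0, 7.0, 3.0])
        np.testing.assert_allclose(tg.map_point(pt, "A", "B"), pt, atol=1e-6)

    def test_affine_valued_field_matches_direct_matrix(self):
        rng = np.random.default_rng(3)
        geom = sa.VolumeGeometry((16, 16, 16), (2, 2, 2))
        m = rigidish(rng)
        tg = sa.TransformationGraph()
        tg.add_field(sa.DeformationFieldTransform("A", "B", affine_field(m, geom), geom))
        pts = rng.uniform(2.0, 28.0, size=(200, 3))
        mapped = tg.map_points(pts, "A", "B")
        direct = pts @ m[:3, :3].T + m[:3, 3]  # oracle: direct application
        assert np.abs(mapped - direct).max() < 1e-3

    def test_outside_field_support(self, geom64):
        tg = sa.TransformationGraph()
        tg.add_field(sa.DeformationFieldTransform("A", "B", affine_field(np.eye(4), geom64), geom64))
        with pytest.raises(OutOfField):
            tg.map_point([-100.0, -100.0, -100.0], "A", "B")

    def test_unreachable(self):
        tg = sa.TransformationGraph()
        tg.add_referential("A")
        tg.add_referential("B")
        with pytest.raises(Unreachable):
            tg.map_point([0, 0, 0], "A", "B")

    def test_inverse_consistency_across_chain(self):
        rng = np.random.default_rng(4)
        tg = sa.TransformationGraph()
        for s, t in [("A", "B"), ("B", "C"), ("C", "D")]:
            tg.add_affine(sa.AffineTransform(s, t, rigidish(rng)))
        pts = rng.normal(size=(20, 3)) * 30
        back = tg.map_points(tg.map_points(pts, "A", "D"), "D", "A")
        assert np.abs(back - pts).max() < 1e-6

    def test_redundant_longer_route_changes_nothing(self):
        rng = np.random.default_rng(5)
        tg = sa.TransformationGraph()
        ab, bc = rigidish(rng), rigidish(rng)
        tg.add_affine(sa.AffineTransform("A", "B", ab))
        tg.add_affine(sa.AffineTransform("B", "C", bc))
        pts = rng.normal(size=(10, 3)) * 20
        before = tg.map_points(pts, "A", "C")
        # consistent redundant route through an extra referential
        half = rigidish(rng)
        tg.add_affine(sa.AffineTransform("A", "X", half))
        tg.add_affine(sa.AffineTransform("X", "C", bc @ ab @ np.linalg.inv(half)))
        after = tg.map_points(pts, "A", "C")
        assert np.abs(after - before).max() < 1e-6


class TestMapMesh:
    def test_identity(self):
        tg = sa.TransformationGraph()
        tg.add_referential("A")
        mesh = sa.TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        out = tg.map_mesh(mesh, "A", "A")
        assert out == mesh

    def test_pure_translation(self):
        tg = sa.TransformationGraph()
        m = np.eye(4)
        m[:3, 3] = [5, -3, 2]
        tg.add_affine(sa.AffineTransform("A", "B", m))
        mesh = sa.TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        out = tg.map_mesh(mesh, "A", "B")
        np.testing.assert_allclose(out.vertices, mesh.vertices + [5, -3, 2])
        np.testing.assert_array_equal(out.triangles, mesh.triangles)

    def test_random_affine_matches_per_vertex_oracle(self):
        rng = np.random.default_rng(6)
        m = rigidish(rng)
        tg = sa.TransformationGraph()
        tg.add_affine(sa.AffineTransform("A", "B", m))
        verts = rng.normal(size=(30, 3)) * 10
        mesh = sa.TriangleMesh(verts, [[i, i + 1, i + 2] for i in range(28)])
        out = tg.map_mesh(mesh, "A", "B")
        expected = np.array([m[:3, :3] @ v + m[:3, 3] for v in verts])
        np.testing.assert_allclose(out.vertices, expected, atol=1e-9)
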