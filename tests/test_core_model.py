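"""Structural-graph model: edition, integrity rules, invariants."""

import numpy as np
import pytest

import structatlas as sa
from structatlas.errors import GeometryMismatch, IdCollision, NotFound


def voxel_node(node_id, geom, voxels, label="unknown"):
    return sa.StructureNode(node_id, label, sa.VoxelSurfaceSet(voxels, geom))


class TestGeometry:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            sa.VolumeGeometry((0, 4, 4), (1, 1, 1))
        with pytest.raises(ValueError):
            sa.VolumeGeometry((4, 4, 4), (1, 0, 1))
        bad = np.eye(4)
        bad[3] = [1, 0, 0, 1]
        with pytest.raises(ValueError):
            sa.VolumeGeometry((4, 4, 4), (1, 1, 1), bad)
        singular = np.diag([1.0, 1.0, 0.0, 1.0])
        with pytest.raises(ValueError):
            sa.VolumeGeometry((4, 4, 4), (1, 1, 1), singular)

    def test_world_round_trip(self, geom64):
        idx = np.array([[1, 2, 3], [10, 20, 30]])
        back = geom64.world_to_voxel_coords(geom64.voxel_to_world_coords(idx))
        np.testing.assert_allclose(back, idx, atol=1e-12)


class TestVoxelSurfaceSet:
    def test_rejects_empty_and_out_of_bounds(self, geom64):
        with pytest.raises(ValueError):
            sa.VoxelSurfaceSet([], geom64)
        with pytest.raises(ValueError):
            sa.VoxelSurfaceSet([(64, 0, 0)], geom64)

    def test_connectivity_detection_matches_brute_force(self, geom64):
        # oracle: breadth-first flood fill over the 26-neighborhood
        rng = np.random.default_rng(3)
        voxels = {tuple(v) for v in rng.integers(5, 15, size=(40, 3))}
        vset = sa.VoxelSurfaceSet(voxels, geom64)

        def flood_components(vox):
            remaining, comps = set(vox), []
            while remaining:
                stack, comp = [next(iter(remaining))], set()
                while stack:
                    v = stack.pop()
                    if v not in remaining:
                        continue
                    remaining.discard(v)
                    comp.add(v)
                    for dx in (-1, 0, 1):
                        for dy in (-1, 0, 1):
                            for dz in (-1, 0, 1):
                                n = (v[0] + dx, v[1] + dy, v[2] + dz)
                                if n in remaining:
                                    stack.append(n)
                comps.append(frozenset(comp))
            return comps

        oracle = flood_components(voxels)
        got = vset.connected_components()
        assert sorted(got, key=sorted) == sorted(oracle, key=sorted)
        assert vset.is_connected() == (len(oracle) == 1)


class TestNodeEdition:
    def test_add_single_node(self, geom64):
        g = sa.StructuralGraph("s")
        g.add_node(voxel_node(1, geom64, [(1, 1, 1)]))
        assert len(g) == 1

    def test_duplicate_id_rejected(self, geom64):
        g = sa.StructuralGraph("s")
        g.add_node(voxel_node(1, geom64, [(1, 1, 1)]))
        with pytest.raises(IdCollision):
            g.add_node(voxel_node(1, geom64, [(2, 2, 2)]))

    def test_geometry_mismatch_rejected(self, geom64):
        g = sa.StructuralGraph("s")
        g.add_node(voxel_node(1, geom64, [(1, 1, 1)]))
        other = sa.VolumeGeometry((32, 32, 32), (2, 2, 2))
        with pytest.raises(GeometryMismatch):
            g.add_node(voxel_node(2, other, [(2, 2, 2)]))

    def test_typical_hemisphere_scale(self, geom64):
        # about 300 folds per hemisphere: sequential adds stay consistent
        g = sa.StructuralGraph("s")
        for i in range(300):
            g.add_node(voxel_node(i, geom64, [(i % 64, i // 64, 0)]))
        assert len(g) == 300
        assert len({n.node_id for n in g}) == 300

    def test_remove_cascades_incident_edges(self, geom64):
        g = sa.StructuralGraph("s")
        g.add_node(voxel_node(1, geom64, [(1, 1, 1)]))
        g.add_node(voxel_node(2, geom64, [(3, 3, 3)]))
        g.add_edge(sa.StructureEdge(0, "junction", (1, 2)))
        g.remove_node(1)
        assert set(g.nodes) == {2} and not g.edges

    def test_remove_missing_raises(self, geom64):
        g = sa.StructuralGraph("s")
        g.add_node(voxel_node(1, geom64, [(1, 1, 1)]))
        with pytest.raises(NotFound):
            g.remove_node(99)

    def test_add_then_remove_is_identity(self, geom64):
        g = sa.StructuralGraph("s")
        g.add_node(voxel_node(1, geom64, [(1, 1, 1)]))
        before_nodes, before_edges = dict(g.nodes), dict(g.edges)
        g.add_node(voxel_node(2, geom64, [(5, 5, 5)]))
        g.remove_node(2)
        assert g.nodes == before_nodes and g.edges == before_edges

    def test_random_removals_match_edge_scan_oracle(self, geom64):
        rng = np.random.default_rng(11)
        g = sa.StructuralGraph("s")
        for i in range(50):
            g.add_node(voxel_node(i, geom64, [(i, i, 0)]))
        eid = 0
        for _ in range(120):
            a, b = rng.choice(50, size=2, replace=False)
            g.add_edge(sa.StructureEdge(eid, "proximity", (int(a), int(b))))
            eid += 1
        for victim in rng.permutation(50)[:25]:
            g.remove_node(int(victim))
            # oracle: full scan over the remaining edge table
            for nid in g.nodes:
                assert len(g.incident_edges(nid)) == sum(
                    1 for e in g.edges.values() if nid in e.endpoints
                )
            assert all(
                end in g.nodes for e in g.edges.values() for end in e.endpoints
            )

    def test_edge_incidence_is_symmetric(self, tiny_cohort):
        graph = next(iter(tiny_cohort[0].subjects.values()))
        for nid in graph.nodes:
            for other in graph.neighbors(nid):
                assert nid in graph.neighbors(other)


class TestValidate:
    def test_generated_graphs_are_clean(self, tiny_cohort):
        cohort, _ = tiny_cohort
        for graph in cohort.subjects.values():
            assert graph.validate(cohort.shared_nomenclature) == []

    def test_dangling_edge_reported(self, geom64):
        g = sa.StructuralGraph("s")
        g.add_node(voxel_node(1, geom64, [(1, 1, 1)]))
        g.add_node(voxel_node(2, geom64, [(3, 3, 3)]))
        g.add_edge(sa.StructureEdge(0, "junction", (1, 2)))
        del g.nodes[2]  # corrupt behind the API's back
        violations = g.validate()
        assert any(
            "edge 0" in v.entity and "2" in v.detail and v.rule == "endpoint-resolvable"
            for v in violations
        )

    def test_disconnected_voxel_set_reported(self, geom64):
        g = sa.StructuralGraph("s")
        g.add_node(voxel_node(1, geom64, [(1, 1, 1), (10, 10, 10)]))
        violations = g.validate()
        assert [v.rule for v in violations] == ["26-connectivity"]
        assert "2 components" in violations[0].detail
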