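"""Label copy/paste and fold splitting."""

import numpy as np
import pytest

import structatlas as sa
from structatlas.editing import CutSpecification
from structatlas.errors import (
    LabelNotInNomenclature,
    NotFound,
    SeedOffStructure,
    UnlabeledSource,
)


@pytest.fixture
def nom():
    return sa.Nomenclature(
        sa.NomenclatureEntry(
            "brain",
            children=[
                sa.NomenclatureEntry("S.C.", color=(255, 0, 0)),
                sa.NomenclatureEntry("S.F.sup.", color=(0, 255, 0)),
            ],
        )
    )


@pytest.fixture
def ribbon_graph(geom64, ribbon):
    g = sa.StructuralGraph("subjA")
    g.add_node(sa.StructureNode(1, "S.C.", ribbon))
    # a neighbor fold next to the ribbon's right half
    curve = np.array([[38.0, 34.0, 50.0], [44.0, 34.0, 50.0]])
    g.add_node(sa.StructureNode(2, "S.F.sup.", sa.generate_fold(curve, 6.0, geometry=geom64)))
    g.add_edge(sa.StructureEdge(0, "proximity", (1, 2)))
    return g


class TestLabeling:
    def test_paste_on_several_nodes(self, ribbon_graph, nom):
        sa.set_label(ribbon_graph, [1, 2], "S.F.sup.", nom)
        assert all(ribbon_graph.nodes[n].label == "S.F.sup." for n in (1, 2))

    def test_label_must_be_in_nomenclature(self, ribbon_graph, nom):
        with pytest.raises(LabelNotInNomenclature):
            sa.set_label(ribbon_graph, [1], "S.ghost.", nom)
        assert ribbon_graph.nodes[1].label == "S.C."  # untouched

    def test_unknown_sentinel_always_allowed(self, ribbon_graph, nom):
        sa.set_label(ribbon_graph, [1], sa.UNKNOWN_LABEL, nom)
        assert ribbon_graph.nodes[1].label == sa.UNKNOWN_LABEL

    def test_missing_node(self, ribbon_graph, nom):
        with pytest.raises(NotFound):
            sa.set_label(ribbon_graph, [99], "S.C.", nom)

    def test_copy_then_cross_subject_paste(self, ribbon_graph, geom64, nom):
        clip = sa.copy_label(ribbon_graph, 1)
        assert clip.label == "S.C."
        assert (clip.source_subject, clip.source_node) == ("subjA", 1)
        other = sa.StructuralGraph("subjB")
        other.add_node(
            sa.StructureNode(7, voxel_rep=sa.VoxelSurfaceSet([(1, 1, 1)], geom64))
        )
        sa.paste_label(other, [7], clip, nom)
        assert other.nodes[7].label == "S.C."

    def test_copy_from_unlabeled_node(self, ribbon_graph):
        sa.set_label(ribbon_graph, [1], sa.UNKNOWN_LABEL)
        with pytest.raises(UnlabeledSource):
            sa.copy_label(ribbon_graph, 1)

    def test_relabel_moves_morphometry_contribution(self, ribbon_graph, nom):
        before = sa.aggregate(ribbon_graph, nom)
        moved = ribbon_graph.nodes[2].properties["size"]
        sa.set_label(ribbon_graph, [2], "S.C.", nom)
        after = sa.aggregate(ribbon_graph, nom)
        # oracle: recompute the aggregation from scratch
        assert after.value("subjA", "S.C.", "size") == pytest.approx(
            before.value("subjA", "S.C.", "size") + moved
        )
        with pytest.raises(KeyError):
            after.value("subjA", "S.F.sup.", "size")


class TestSplit:
    def test_ribbon_split_partitions_exactly(self, ribbon_graph, ribbon):
        parent_voxels = ribbon.voxels
        g, (a, b) = sa.split_node(ribbon_graph, CutSpecification(1, [[30.0, 30.0, 45.0]]))
        va, vb = g.nodes[a].voxel_rep, g.nodes[b].voxel_rep
        assert va.voxels | vb.voxels == parent_voxels
        assert not (va.voxels & vb.voxels)
        assert va.is_connected() and vb.is_connected()
        # oracle: the ribbon spans x in 20..39; a depth-direction cut through
        # the seed removes the x=30 column (10 voxels), leaving components of
        # 100 and 90 voxels; the equidistant column goes to the larger one
        left = {v for v in parent_voxels if v[0] < 30}
        right = {v for v in parent_voxels if v[0] > 30}
        spine = {v for v in parent_voxels if v[0] == 30}
        assert {len(va), len(vb)} == {len(left) + len(spine), len(right)}

    def test_split_updates_topology(self, ribbon_graph):
        n_before = len(ribbon_graph)
        g, (a, b) = sa.split_node(ribbon_graph, CutSpecification(1, [[30.0, 30.0, 45.0]]))
        assert len(g) == n_before + 1
        assert any(
            e.kind == sa.EdgeKind.JUNCTION and set(e.endpoints) == {a, b}
            for e in g.edges.values()
        )
        # the former proximity edge re-homed to the child nearer to node 2
        rehomed = [e for e in g.edges.values() if 2 in e.endpoints]
        assert len(rehomed) == 1
        child = rehomed[0].other(2)
        assert child in (a, b)
        assert g.validate() == []

    def test_children_inherit_parent_label(self, ribbon_graph):
        g, (a, b) = sa.split_node(ribbon_graph, CutSpecification(1, [[30.0, 30.0, 45.0]]))
        assert g.nodes[a].label == g.nodes[b].label == "S.C."

    def test_seed_far_from_fold(self, ribbon_graph):
        with pytest.raises(SeedOffStructure):
            sa.split_node(ribbon_graph, CutSpecification(1, [[5.0, 5.0, 5.0]]))

    def test_multi_seed_cut(self, ribbon_graph, ribbon):
        seeds = [[30.0, 30.0, 49.0], [30.0, 30.0, 45.0], [30.0, 30.0, 41.0]]
        g, (a, b) = sa.split_node(ribbon_graph, CutSpecification(1, seeds))
        assert g.nodes[a].voxel_rep.voxels | g.nodes[b].voxel_rep.voxels == ribbon.voxels


class TestMerge:
    def test_split_then_merge_restores_voxels(self, ribbon_graph, ribbon):
        non_incident = {
            eid for eid, e in ribbon_graph.edges.items() if 1 not in e.endpoints
        }
        g, (a, b) = sa.split_node(ribbon_graph, CutSpecification(1, [[30.0, 30.0, 45.0]]))
        sa.merge_nodes(g, a, b)
        assert g.nodes[a].voxel_rep.voxels == ribbon.voxels
        assert non_incident <= set(g.edges)
        assert g.validate() == []

    def test_merge_keeps_first_label(self, geom64):
        g = sa.StructuralGraph("s")
        g.add_node(sa.StructureNode(1, "S.C.", sa.VoxelSurfaceSet([(1, 1, 1)], geom64)))
        g.add_node(sa.StructureNode(2, "S.F.sup.", sa.VoxelSurfaceSet([(2, 1, 1)], geom64)))
        sa.merge_nodes(g, 1, 2)
        assert g.nodes[1].label == "S.C."

    def test_merged_count_is_sum(self, ribbon_graph):
        g, (a, b) = sa.split_node(ribbon_graph, CutSpecification(1, [[30.0, 30.0, 45.0]]))
        na, nb = len(g.nodes[a].voxel_rep), len(g.nodes[b].voxel_rep)
        sa.merge_nodes(g, a, b)
        assert len(g.nodes[a].voxel_rep) == na + nb  # disjoint by construction
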