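"""Structure-level edition: label copy/paste and fold splitting.

Labeling mimics the annotation workflow of a structural atlas editor: a
label is picked from one graph node — in the same subject or another one —
and pasted onto a series of selected nodes, validated against the shared
nomenclature.

Splitting cuts one fold node in two along a cutting line going through one
or several user-given points, then updates the graph topology: the two new
nodes partition the parent's voxel set exactly, former edges are re-homed to
the nearer child, and a junction edge joins the children.  Mesh
representations of the parent are dropped (they no longer match either
child and must be re-meshed downstream).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core_model import (
    EdgeKind,
    StructureEdge,
    StructureNode,
    StructuralGraph,
    UNKNOWN_LABEL,
    VoxelSurfaceSet,
)
from .errors import (
    AmbiguousCut,
    CutIneffective,
    LabelNotInNomenclature,
    NotFound,
    NoRepresentation,
    SeedOffStructure,
    UnlabeledSource,
)
from .morphometry import _principal_axes
from .nomenclature import Nomenclature

#: A seed must fall within this many voxels of the fold's set to snap.
SEED_SNAP_RADIUS_VOXELS = 2.0

# face neighbors first: equal-length BFS paths then prefer axis-aligned
# steps, which produce straight cut spines that actually separate a sheet
_NEIGHBORS_26 = [
    np.array(d)
    for d in sorted(
        (d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)),
        key=lambda d: (sum(c != 0 for c in d), d),
    )
]


@dataclass(frozen=True)
class LabelClipboard:
    """A label picked from a graph node, with provenance."""

    label: str
    source_subject: str
    source_node: int

    def __post_init__(self):
        if not self.label:
            raise ValueError("clipboard label cannot be empty")


@dataclass
class CutSpecification:
    """A cutting line through a fold: ordered seed points in world mm."""

    node_id: int
    seed_points: Sequence = field(default_factory=list)

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.seed_points, dtype=float))
        if pts.size == 0 or pts.shape[1] != 3:
            raise ValueError("cut needs at least one (x, y, z) seed point")
        self.seed_points = pts


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------

def set_label(
    graph: StructuralGraph,
    node_ids: Sequence[int],
    label: str,
    nomenclature: Optional[Nomenclature] = None,
) -> StructuralGraph:
    """Assign ``label`` to every listed node; nothing else changes.

    With a nomenclature attached, the label must occur in it (the UNKNOWN
    sentinel is always accepted — it *un*-identifies a fold).
    """
    if (
        nomenclature is not None
        and label != UNKNOWN_LABEL
        and not nomenclature.contains(label)
    ):
        raise LabelNotInNomenclature(f"label {label!r} not in nomenclature")
    for nid in node_ids:
        if nid not in graph.nodes:
            raise NotFound(f"node id {nid} not in graph")
    for nid in node_ids:
        graph.nodes[nid].label = label
    return graph


def copy_label(
    graph: StructuralGraph, node_id: int, allow_unknown: bool = False
) -> LabelClipboard:
    """Pick a node's label into a clipboard (with provenance)."""
    if node_id not in graph.nodes:
        raise NotFound(f"node id {node_id} not in graph")
    node = graph.nodes[node_id]
    if node.label == UNKNOWN_LABEL and not allow_unknown:
        raise UnlabeledSource(f"node {node_id} carries no identification")
    return LabelClipboard(node.label, graph.subject_id, node_id)


def paste_label(
    graph: StructuralGraph,
    node_ids: Sequence[int],
    clipboard: LabelClipboard,
    nomenclature: Optional[Nomenclature] = None,
) -> StructuralGraph:
    """Paste a clipboard label onto selected nodes (possibly another subject)."""
    return set_label(graph, node_ids, clipboard.label, nomenclature)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def _shortest_inset_path(voxset: frozenset, start: tuple, goal: tuple) -> list[tuple]:
    """Breadth-first shortest 26-connected path inside a voxel set."""
    if start == goal:
        return [start]
    prev = {start: None}
    queue = deque([np.array(start)])
    while queue:
        cur = queue.popleft()
        for off in _NEIGHBORS_26:
            nxt = tuple((cur + off).tolist())
            if nxt in prev or nxt not in voxset:
                continue
            prev[nxt] = tuple(cur.tolist())
            if nxt == goal:
                path = [nxt]
                while path[-1] is not None:
                    path.append(prev[path[-1]])
                return path[-2::-1]
            queue.append(np.array(nxt))
    raise CutIneffective(f"seeds {start} and {goal} not connected inside the fold")


def _extend_spine(
    spine: list[tuple], voxset: frozenset, direction_vox: np.ndarray
) -> list[tuple]:
    """Extend the cut spine at both ends along the fold's depth direction
    until the walk leaves the voxel set."""
    spine_centroid = np.mean(np.array(spine, dtype=float), axis=0)
    extended = list(spine)
    for i, end in enumerate((spine[0], spine[-1])):
        away = np.dot(direction_vox, np.array(end, dtype=float) - spine_centroid)
        if abs(away) > 1e-9:
            sign = 1.0 if away > 0 else -1.0
        else:  # single-point or symmetric spine: take both directions
            sign = -1.0 if i == 0 else 1.0
        step = sign * direction_vox
        pos = np.array(end, dtype=float)
        for _ in range(4 * 256):  # hard cap; leaves any finite grid
            pos = pos + 0.5 * step
            vox = tuple(int(round(c)) for c in pos)
            if vox not in voxset:
                break
            if vox not in extended:
                extended.append(vox)
    return extended


def split_node(
    graph: StructuralGraph, cut: CutSpecification
) -> tuple[StructuralGraph, tuple[int, int]]:
    """Split one fold node in two along a cutting line.

    Procedure: each seed snaps to its nearest voxel of the fold; consecutive
    snapped seeds are joined by shortest 26-connected in-set paths forming
    the cut spine; the spine is extended at both ends along the fold's depth
    direction (second principal axis of the voxel cloud) until it leaves the
    set; removing the spine must leave exactly two 26-connected components,
    which become the children.  Spine voxels are reassigned to the nearer
    child (ties to the larger one) so the children partition the parent
    exactly.  Former edges re-home to the child nearest to the former
    neighbor; a junction edge joins the two children; the parent (and its
    mesh) is removed.

    Returns the mutated graph and the two new node ids.
    """
    if cut.node_id not in graph.nodes:
        raise NotFound(f"node id {cut.node_id} not in graph")
    parent = graph.nodes[cut.node_id]
    if parent.voxel_rep is None:
        raise NoRepresentation(f"node {cut.node_id} has no voxel representation")
    rep = parent.voxel_rep
    geom = rep.geometry
    arr = rep.array

    # 1. snap seeds (given in world mm) to nearest voxels of the set
    seeds_vox = np.atleast_2d(geom.world_to_voxel_coords(cut.seed_points))
    tree = cKDTree(arr.astype(float))
    dists, idx = tree.query(seeds_vox)
    if dists.min() > SEED_SNAP_RADIUS_VOXELS:
        raise SeedOffStructure(
            f"nearest seed is {dists.min():.1f} voxels from the fold "
            f"(limit {SEED_SNAP_RADIUS_VOXELS})"
        )
    snapped = [tuple(int(c) for c in arr[i]) for i in idx]

    # 2. cut spine: shortest in-set paths between consecutive snapped seeds
    spine: list[tuple] = [snapped[0]]
    for a, b in zip(snapped, snapped[1:]):
        for vox in _shortest_inset_path(rep.voxels, a, b)[1:]:
            if vox not in spine:
                spine.append(vox)

    # 3. extend along the depth direction (second principal axis), converted
    #    from world to voxel space
    axes = _principal_axes(geom.voxel_to_world_coords(arr))
    depth_vox = np.linalg.inv(geom.voxel_to_world[:3, :3]) @ axes[1]
    depth_vox = depth_vox / np.linalg.norm(depth_vox)
    spine = _extend_spine(spine, rep.voxels, depth_vox)

    # 4. remove the spine, label what remains
    remaining = rep.voxels - set(spine)
    if not remaining:
        raise CutIneffective("cut spine covers the whole fold")
    comps = VoxelSurfaceSet(remaining, geom).connected_components()
    if len(comps) == 1:
        raise CutIneffective("cut left the fold in one connected piece")
    if len(comps) > 2:
        raise AmbiguousCut(f"cut produced {len(comps)} pieces, expected 2")
    comp_a, comp_b = comps  # comps sorted largest first

    # 5. hand each spine voxel back to the nearer component (ties → larger)
    tree_a = cKDTree(np.array(sorted(comp_a), dtype=float))
    tree_b = cKDTree(np.array(sorted(comp_b), dtype=float))
    child_a, child_b = set(comp_a), set(comp_b)
    spine_arr = np.array(spine, dtype=float)
    da, _ = tree_a.query(spine_arr)
    db, _ = tree_b.query(spine_arr)
    for vox, near_a, near_b in zip(spine, da, db):
        (child_a if near_a <= near_b else child_b).add(vox)

    # nearest-distance reassignment can strand a few spine voxels away from
    # their child's core; push stranded pieces to the other child
    def _repair(own: set, core: frozenset, other: set):
        pieces = VoxelSurfaceSet(own, geom).connected_components()
        if len(pieces) > 1:
            for piece in pieces:
                if not (piece & core):
                    own -= piece
                    other |= piece

    _repair(child_a, comp_a, child_b)
    _repair(child_b, comp_b, child_a)

    id_a = graph.next_node_id()
    id_b = id_a + 1
    node_a = StructureNode(id_a, parent.label, VoxelSurfaceSet(child_a, geom))
    node_b = StructureNode(id_b, parent.label, VoxelSurfaceSet(child_b, geom))

    # 6. re-derive topology: each former edge reattaches to the nearer child
    former = graph.incident_edges(cut.node_id)
    rehome: list[tuple[StructureEdge, int]] = []
    arr_a = node_a.voxel_rep.world_coords()
    arr_b = node_b.voxel_rep.world_coords()
    ta, tb = cKDTree(arr_a), cKDTree(arr_b)
    for edge in former:
        other = graph.nodes[edge.other(cut.node_id)]
        if other.voxel_rep is not None:
            pts = other.voxel_rep.world_coords()
        elif other.mesh is not None:
            pts = other.mesh.vertices
        else:  # pragma: no cover - node invariants forbid this
            raise NoRepresentation(f"node {other.node_id} has no representation")
        # minimum voxel-pair (world) distance to each child
        dist_a = float(ta.query(pts)[0].min())
        dist_b = float(tb.query(pts)[0].min())
        rehome.append((edge, id_a if dist_a <= dist_b else id_b))

    graph.remove_node(cut.node_id)  # also drops the former edges
    graph.add_node(node_a)
    graph.add_node(node_b)
    for edge, child in rehome:
        keep = edge.endpoints[0] if edge.endpoints[1] == cut.node_id else edge.endpoints[1]
        graph.add_edge(
            StructureEdge(edge.edge_id, edge.kind, (keep, child), dict(edge.properties))
        )
    graph.add_edge(
        StructureEdge(graph.next_edge_id(), EdgeKind.JUNCTION, (id_a, id_b))
    )
    return graph, (id_a, id_b)


def merge_nodes(
    graph: StructuralGraph, node_id_a: int, node_id_b: int
) -> StructuralGraph:
    """Merge two fold nodes into one (the inverse of a split).

    The merged node keeps ``node_id_a`` and its label; voxel sets are
    unioned; edges of both nodes re-home to the merged node, edges between
    the pair disappear, and meshes are dropped (stale after the merge).
    """
    for nid in (node_id_a, node_id_b):
        if nid not in graph.nodes:
            raise NotFound(f"node id {nid} not in graph")
    a, b = graph.nodes[node_id_a], graph.nodes[node_id_b]
    if a.voxel_rep is None or b.voxel_rep is None:
        raise NoRepresentation("merge needs voxel representations on both nodes")
    if a.voxel_rep.geometry != b.voxel_rep.geometry:
        raise NotFound("nodes live on different volume geometries")
    merged = VoxelSurfaceSet(a.voxel_rep.voxels | b.voxel_rep.voxels, a.voxel_rep.geometry)

    rehomed: dict[tuple, StructureEdge] = {}
    for edge in graph.incident_edges(node_id_a) + graph.incident_edges(node_id_b):
        other = edge.other(node_id_a if node_id_a in edge.endpoints else node_id_b)
        if other in (node_id_a, node_id_b):
            continue  # inter-pair edge disappears
        key = (min(other, node_id_a), max(other, node_id_a), edge.kind)
        if key not in rehomed:
            rehomed[key] = StructureEdge(
                edge.edge_id, edge.kind, (other, node_id_a), dict(edge.properties)
            )
    graph.remove_node(node_id_a)
    graph.remove_node(node_id_b)
    graph.add_node(StructureNode(node_id_a, a.label, merged, properties=dict()))
    for edge in rehomed.values():
        graph.add_edge(edge)
    return graph
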