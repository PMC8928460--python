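"""Structural-graph data model for fold-based brain representations.

A structural graph holds one subject's elementary cortical folds as nodes and
their topographic relations (junction / proximity) as edges.  Each fold is
represented by the voxel-set "negative cast" of the sulcal cerebrospinal-fluid
space — a set of voxels with a surface geometry — and/or by a triangle mesh.
All voxel representations of one graph live on a single shared volume grid,
bound to the subject's native referential.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Optional

import numpy as np
from scipy import ndimage

from .errors import GeometryMismatch, IdCollision, NotFound

#: Canonical sentinel for a fold that has not been identified yet.
UNKNOWN_LABEL = "unknown"

#: 3x3x3 structuring element: 26-neighbourhood (vertex connectivity).
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


class Hemisphere(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    BOTH = "both"


class EdgeKind(str, Enum):
    JUNCTION = "junction"
    PROXIMITY = "proximity"


class VolumeGeometry:
    """Sampling grid of a 3D volume: shape, voxel size and voxel→world map.

    ``voxel_to_world`` maps homogeneous 0-based voxel indices ``(i, j, k, 1)``
    to world millimetre coordinates (the voxel centre convention used by the
    common volume formats).
    """

    __slots__ = ("shape", "voxel_size", "voxel_to_world", "_world_to_voxel")

    def __init__(self, shape, voxel_size, voxel_to_world=None):
        shape = tuple(int(s) for s in shape)
        voxel_size = tuple(float(v) for v in voxel_size)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be three entries >= 1, got {shape}")
        if len(voxel_size) != 3 or any(v <= 0 for v in voxel_size):
            raise ValueError(f"voxel_size must be three positive reals, got {voxel_size}")
        if voxel_to_world is None:
            voxel_to_world = np.diag(list(voxel_size) + [1.0])
        voxel_to_world = np.asarray(voxel_to_world, dtype=float)
        if voxel_to_world.shape != (4, 4):
            raise ValueError("voxel_to_world must be a 4x4 matrix")
        if not np.array_equal(voxel_to_world[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValueError("last row of voxel_to_world must be (0, 0, 0, 1)")
        if abs(np.linalg.det(voxel_to_world[:3, :3])) < 1e-12:
            raise ValueError("upper-left 3x3 block of voxel_to_world is singular")
        self.shape = shape
        self.voxel_size = voxel_size
        self.voxel_to_world = voxel_to_world
        self._world_to_voxel = np.linalg.inv(voxel_to_world)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    def voxel_to_world_coords(self, indices) -> np.ndarray:
        """Map (N, 3) voxel indices (or one triple) to world mm coordinates."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        hom = np.c_[idx, np.ones(len(idx))]
        out = hom @ self.voxel_to_world.T
        return out[:, :3] if np.ndim(indices) > 1 else out[0, :3]

    def world_to_voxel_coords(self, points) -> np.ndarray:
        """Map world mm coordinates to continuous voxel coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        hom = np.c_[pts, np.ones(len(pts))]
        out = hom @ self._world_to_voxel.T
        return out[:, :3] if np.ndim(points) > 1 else out[0, :3]

    def contains_index(self, index) -> bool:
        return all(0 <= int(index[a]) < self.shape[a] for a in range(3))

    def __eq__(self, other):
        if not isinstance(other, VolumeGeometry):
            return NotImplemented
        return (
            self.shape == other.shape
            and self.voxel_size == other.voxel_size
            and np.array_equal(self.voxel_to_world, other.voxel_to_world)
        )

    def __hash__(self):
        return hash((self.shape, self.voxel_size, self.voxel_to_world.tobytes()))

    def __repr__(self):
        return f"VolumeGeometry(shape={self.shape}, voxel_size={self.voxel_size})"


class VoxelSurfaceSet:
    """Voxel-based representation of one fold: a set of 0-based voxel indices
    on a :class:`VolumeGeometry` grid.

    A well-formed fold is non-empty, in-bounds, and forms a single
    26-connected component (reported by :func:`validate_graph`, not enforced
    at construction so that malformed sets can be represented and flagged).
    """

    __slots__ = ("voxels", "geometry", "_array")

    def __init__(self, voxels: Iterable, geometry: VolumeGeometry):
        vox = frozenset(tuple(int(c) for c in v) for v in voxels)
        if not vox:
            raise ValueError("a VoxelSurfaceSet cannot be empty")
        for v in vox:
            if len(v) != 3:
                raise ValueError(f"voxel index must be a triple, got {v}")
            if not geometry.contains_index(v):
                raise ValueError(f"voxel index {v} outside grid shape {geometry.shape}")
        self.voxels = vox
        self.geometry = geometry
        self._array: Optional[np.ndarray] = None

    @property
    def array(self) -> np.ndarray:
        """Sorted (N, 3) int array of the voxel indices (lexicographic)."""
        if self._array is None:
            self._array = np.array(sorted(self.voxels), dtype=np.int64)
        return self._array

    def __len__(self):
        return len(self.voxels)

    def __contains__(self, item):
        return tuple(item) in self.voxels

    def __eq__(self, other):
        if not isinstance(other, VoxelSurfaceSet):
            return NotImplemented
        return self.voxels == other.voxels and self.geometry == other.geometry

    def __hash__(self):
        return hash((self.voxels, self.geometry))

    def world_coords(self) -> np.ndarray:
        """World mm coordinates of the voxel centres, (N, 3)."""
        return self.geometry.voxel_to_world_coords(self.array)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        arr = self.array
        return arr.min(axis=0), arr.max(axis=0)

    def connected_components(self) -> list[frozenset]:
        """26-connected components of the set, largest first."""
        lo, hi = self.bounding_box()
        sub = np.zeros(tuple(hi - lo + 1), dtype=np.uint8)
        local = self.array - lo
        sub[local[:, 0], local[:, 1], local[:, 2]] = 1
        labels, n = ndimage.label(sub, structure=CONNECTIVITY_26)
        comps: list[list] = [[] for _ in range(n)]
        lab = labels[local[:, 0], local[:, 1], local[:, 2]]
        for v, l in zip(self.array, lab):
            comps[l - 1].append(tuple(int(c) for c in v))
        comps.sort(key=lambda c: (-len(c), min(c)))
        return [frozenset(c) for c in comps]

    def is_connected(self) -> bool:
        return len(self.connected_components()) == 1


class TriangleMesh:
    """Triangle mesh in world mm coordinates."""

    __slots__ = ("vertices", "triangles")

    def __init__(self, vertices, triangles):
        vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
        triangles = np.asarray(triangles, dtype=np.int64).reshape(-1, 3)
        if triangles.size:
            if triangles.min() < 0 or triangles.max() >= len(vertices):
                raise ValueError("triangle index out of range")
            degen = (
                (triangles[:, 0] == triangles[:, 1])
                | (triangles[:, 1] == triangles[:, 2])
                | (triangles[:, 0] == triangles[:, 2])
            )
            if degen.any():
                raise ValueError(f"{int(degen.sum())} degenerate triangle(s)")
        self.vertices = vertices
        self.triangles = triangles

    def __eq__(self, other):
        if not isinstance(other, TriangleMesh):
            return NotImplemented
        return np.array_equal(self.vertices, other.vertices) and np.array_equal(
            self.triangles, other.triangles
        )

    def __repr__(self):
        return f"TriangleMesh({len(self.vertices)} vertices, {len(self.triangles)} triangles)"


@dataclass
class StructureNode:
    """One elementary structure (a cortical fold): identifier, label,
    geometric representations and scalar measurement properties."""

    node_id: int
    label: str = UNKNOWN_LABEL
    voxel_rep: Optional[VoxelSurfaceSet] = None
    mesh: Optional[TriangleMesh] = None
    properties: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.node_id = int(self.node_id)
        if self.voxel_rep is None and self.mesh is None:
            raise ValueError(f"node {self.node_id}: needs a voxel_rep or a mesh")


@dataclass
class StructureEdge:
    """Topographic relation between two folds (junction or proximity)."""

    edge_id: int
    kind: EdgeKind
    endpoints: tuple[int, int]
    properties: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.edge_id = int(self.edge_id)
        self.kind = EdgeKind(self.kind)
        a, b = (int(e) for e in self.endpoints)
        if a == b:
            raise ValueError(f"edge {self.edge_id}: endpoints must be distinct")
        self.endpoints = (a, b)

    def other(self, node_id: int) -> int:
        a, b = self.endpoints
        return b if node_id == a else a


@dataclass(frozen=True)
class Violation:
    """One integrity-rule violation, naming the offending entity."""

    entity: str
    rule: str
    detail: str

    def __str__(self):
        return f"{self.entity}: {self.rule} ({self.detail})"


class StructuralGraph:
    """Per-subject graph of structure nodes and topographic edges.

    All voxel representations share one :class:`VolumeGeometry`; the graph is
    bound to the subject's native referential by ``referential_id``.
    """

    def __init__(
        self,
        subject_id: str,
        hemisphere: Hemisphere | str = Hemisphere.LEFT,
        referential_id: str = "",
        metadata: Optional[Mapping[str, str]] = None,
    ):
        self.subject_id = str(subject_id)
        self.hemisphere = Hemisphere(hemisphere)
        self.referential_id = referential_id or f"native:{subject_id}"
        self.nodes: dict[int, StructureNode] = {}
        self.edges: dict[int, StructureEdge] = {}
        self.metadata: dict[str, str] = dict(metadata or {})

    # -- geometry ---------------------------------------------------------
    @property
    def geometry(self) -> Optional[VolumeGeometry]:
        """The shared volume geometry of the graph's voxel sets, if any."""
        for node in self.nodes.values():
            if node.voxel_rep is not None:
                return node.voxel_rep.geometry
        return None

    # -- node / edge edition ---------------------------------------------
    def add_node(self, node: StructureNode) -> "StructuralGraph":
        if node.node_id in self.nodes:
            raise IdCollision(f"node id {node.node_id} already present")
        if node.voxel_rep is not None:
            geom = self.geometry
            if geom is not None and node.voxel_rep.geometry != geom:
                raise GeometryMismatch(
                    f"node {node.node_id}: voxel geometry differs from graph geometry"
                )
        self.nodes[node.node_id] = node
        return self

    def remove_node(self, node_id: int) -> "StructuralGraph":
        if node_id not in self.nodes:
            raise NotFound(f"node id {node_id} not in graph")
        del self.nodes[node_id]
        for eid in [e.edge_id for e in self.edges.values() if node_id in e.endpoints]:
            del self.edges[eid]
        return self

    def add_edge(self, edge: StructureEdge) -> "StructuralGraph":
        if edge.edge_id in self.edges:
            raise IdCollision(f"edge id {edge.edge_id} already present")
        for end in edge.endpoints:
            if end not in self.nodes:
                raise NotFound(f"edge {edge.edge_id}: endpoint node {end} not in graph")
        self.edges[edge.edge_id] = edge
        return self

    def remove_edge(self, edge_id: int) -> "StructuralGraph":
        if edge_id not in self.edges:
            raise NotFound(f"edge id {edge_id} not in graph")
        del self.edges[edge_id]
        return self

    def next_node_id(self) -> int:
        return max(self.nodes, default=-1) + 1

    def next_edge_id(self) -> int:
        return max(self.edges, default=-1) + 1

    # -- queries ----------------------------------------------------------
    def incident_edges(self, node_id: int) -> list[StructureEdge]:
        if node_id not in self.nodes:
            raise NotFound(f"node id {node_id} not in graph")
        return [e for e in self.edges.values() if node_id in e.endpoints]

    def neighbors(self, node_id: int) -> set[int]:
        return {e.other(node_id) for e in self.incident_edges(node_id)}

    def nodes_with_label(self, label: str) -> list[StructureNode]:
        return [n for n in self.nodes.values() if n.label == label]

    def __iter__(self) -> Iterator[StructureNode]:
        return iter(self.nodes.values())

    def __len__(self):
        return len(self.nodes)

    # -- integrity --------------------------------------------------------
    def validate(self, nomenclature=None) -> list[Violation]:
        """Check every model invariant; return one descriptor per violation.

        An empty list means the graph is well formed.  When a nomenclature is
        given, node labels other than the UNKNOWN sentinel must occur in it.
        """
        violations: list[Violation] = []
        geom = self.geometry
        for node in self.nodes.values():
            ent = f"node {node.node_id}"
            if node.voxel_rep is None and node.mesh is None:
                violations.append(Violation(ent, "representation", "no voxel_rep nor mesh"))
            if node.voxel_rep is not None:
                if node.voxel_rep.geometry != geom:
                    violations.append(
                        Violation(ent, "shared-geometry", "voxel geometry differs from graph's")
                    )
                elif not node.voxel_rep.is_connected():
                    n = len(node.voxel_rep.connected_components())
                    violations.append(
                        Violation(ent, "26-connectivity", f"voxel set has {n} components")
                    )
            if (
                nomenclature is not None
                and node.label != UNKNOWN_LABEL
                and not nomenclature.contains(node.label)
            ):
                violations.append(
                    Violation(ent, "label-in-nomenclature", f"label {node.label!r} unknown")
                )
        for edge in self.edges.values():
            ent = f"edge {edge.edge_id}"
            for end in edge.endpoints:
                if end not in self.nodes:
                    violations.append(
                        Violation(ent, "endpoint-resolvable", f"node {end} absent")
                    )
        return violations
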