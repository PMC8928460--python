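"""Decentralized coordinate-system graph.

Every piece of data lives in its own native coordinate system (a
*referential*); transforms join referentials without assuming any central
template space.  Affine transforms are invertible and traversed in either
direction; deformation-field transforms are directed (non-linear warps are
not invertible everywhere) and are only ever applied forward.  Coordinates
are mapped between any two connected referentials by composing the
fewest-edges chain on the fly.
"""

from __future__ import annotations

import heapq
from typing import Literal, Optional, Sequence, Union

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .core_model import TriangleMesh, VolumeGeometry
from .errors import NotComposable, NotFound, OutOfField, Unreachable

Direction = Literal["forward", "inverse"]


class Referential:
    """A named coordinate system."""

    __slots__ = ("ref_id",)

    def __init__(self, ref_id: str):
        if not ref_id:
            raise ValueError("referential id cannot be empty")
        self.ref_id = str(ref_id)

    def __eq__(self, other):
        return isinstance(other, Referential) and self.ref_id == other.ref_id

    def __hash__(self):
        return hash(self.ref_id)

    def __repr__(self):
        return f"Referential({self.ref_id!r})"


class AffineTransform:
    """Affine mm→mm transform between two referentials (4x4 homogeneous)."""

    __slots__ = ("source", "target", "matrix", "_inverse")

    def __init__(self, source: str, target: str, matrix):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if not np.allclose(matrix[3], [0, 0, 0, 1], atol=1e-12):
            raise ValueError("last row of an affine must be (0, 0, 0, 1)")
        if abs(np.linalg.det(matrix[:3, :3])) < 1e-12:
            raise ValueError("affine 3x3 block is singular")
        self.source = str(source)
        self.target = str(target)
        self.matrix = matrix
        self._inverse: Optional[np.ndarray] = None

    @property
    def inverse_matrix(self) -> np.ndarray:
        if self._inverse is None:
            self._inverse = np.linalg.inv(self.matrix)
        return self._inverse

    def apply(self, points: np.ndarray, direction: Direction = "forward") -> np.ndarray:
        m = self.matrix if direction == "forward" else self.inverse_matrix
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ m[:3, :3].T + m[:3, 3]
        return out if np.ndim(points) > 1 else out[0]

    def __repr__(self):
        return f"AffineTransform({self.source!r} -> {self.target!r})"


class DeformationFieldTransform:
    """Dense non-linear transform sampled on a grid in source space.

    ``field`` has shape ``(*geometry.shape, 3)`` and stores, at each source
    voxel, the *absolute target-space mm coordinates* of that voxel (not a
    displacement).  The transform is directed: it is never traversed in
    reverse, since such warps may not be invertible at every point.
    Off-grid points are mapped by trilinear interpolation of the field;
    points outside the sampled support raise :class:`OutOfField`.
    """

    __slots__ = ("source", "target", "field", "geometry", "_interp")

    def __init__(self, source: str, target: str, field, geometry: VolumeGeometry):
        field = np.asarray(field, dtype=float)
        if field.ndim != 4 or field.shape[-1] != 3:
            raise ValueError(f"field must have shape (nx, ny, nz, 3), got {field.shape}")
        if field.shape[:3] != geometry.shape:
            raise ValueError("field grid does not match its geometry shape")
        self.source = str(source)
        self.target = str(target)
        self.field = field
        self.geometry = geometry
        self._interp = None

    @classmethod
    def from_displacements(cls, source, target, displacements, geometry):
        """Build from a displacement-convention field (target = source + d)."""
        displacements = np.asarray(displacements, dtype=float)
        shape = geometry.shape
        grid = np.stack(
            np.meshgrid(*(np.arange(s) for s in shape), indexing="ij"), axis=-1
        ).reshape(-1, 3)
        world = geometry.voxel_to_world_coords(grid).reshape(*shape, 3)
        return cls(source, target, world + displacements, geometry)

    def apply(self, points: np.ndarray, direction: Direction = "forward") -> np.ndarray:
        if direction != "forward":
            raise NotComposable("deformation fields are directed; no inverse traversal")
        if self._interp is None:
            axes = tuple(np.arange(s, dtype=float) for s in self.geometry.shape)
            self._interp = RegularGridInterpolator(
                axes, self.field, method="linear", bounds_error=True
            )
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        vox = self.geometry.world_to_voxel_coords(pts)
        vox = np.atleast_2d(vox)
        try:
            out = self._interp(vox)
        except ValueError as exc:
            raise OutOfField(f"point outside deformation-field support: {exc}") from None
        return out if np.ndim(points) > 1 else out[0]

    def __repr__(self):
        return f"DeformationFieldTransform({self.source!r} -> {self.target!r})"


Transform = Union[AffineTransform, DeformationFieldTransform]
PathStep = tuple[Transform, Direction]


class TransformationGraph:
    """Referentials joined by affine or deformation-field transforms.

    Chains between two referentials are resolved with the fewest edges;
    among equally short chains the one whose traversed referential-id
    sequence is lexicographically smallest wins, so resolution is
    deterministic.
    """

    def __init__(self):
        self.referentials: dict[str, Referential] = {}
        self.affines: list[AffineTransform] = []
        self.fields: list[DeformationFieldTransform] = []

    # -- construction ------------------------------------------------------
    def add_referential(self, ref: Union[Referential, str]) -> Referential:
        if isinstance(ref, str):
            ref = Referential(ref)
        self.referentials.setdefault(ref.ref_id, ref)
        return self.referentials[ref.ref_id]

    def _check_endpoints(self, t: Transform):
        if t.source == t.target:
            raise ValueError(f"self-loop transform on {t.source!r} not allowed")
        self.add_referential(t.source)
        self.add_referential(t.target)

    def add_affine(self, t: AffineTransform) -> AffineTransform:
        self._check_endpoints(t)
        self.affines.append(t)
        return t

    def add_field(self, t: DeformationFieldTransform) -> DeformationFieldTransform:
        self._check_endpoints(t)
        self.fields.append(t)
        return t

    # -- resolution --------------------------------------------------------
    def _adjacency(self) -> dict[str, list[tuple[str, Transform, Direction, int]]]:
        adj: dict[str, list] = {r: [] for r in self.referentials}
        for i, t in enumerate(self.affines):
            adj[t.source].append((t.target, t, "forward", i))
            adj[t.target].append((t.source, t, "inverse", i))
        for i, t in enumerate(self.fields):
            adj[t.source].append((t.target, t, "forward", len(self.affines) + i))
        return adj

    def resolve_path(self, source: str, target: str) -> Optional[list[PathStep]]:
        """Shortest transform chain from ``source`` to ``target``.

        Returns an ordered list of ``(transform, direction)`` steps, the
        empty list for ``source == target``, or None when the referentials
        are not connected.  Affine edges are traversable both ways (the
        inverse matrix is used); field edges only forward.
        """
        for ref in (source, target):
            if ref not in self.referentials:
                raise NotFound(f"referential {ref!r} not registered")
        if source == target:
            return []
        adj = self._adjacency()
        # Dijkstra on (hop count, traversed ref-id sequence): unique minimum.
        # A push counter breaks remaining ties (parallel edges) by
        # registration order without comparing transform objects.
        best: dict[str, tuple] = {}
        counter = 0
        heap: list[tuple] = [(0, (source,), 0, source, [])]
        while heap:
            dist, refpath, _tick, ref, steps = heapq.heappop(heap)
            if ref in best and best[ref] <= (dist, refpath):
                continue
            best[ref] = (dist, refpath)
            if ref == target:
                return steps
            for nxt, transform, direction, _idx in sorted(
                adj[ref], key=lambda e: (e[0], e[3])
            ):
                if nxt in refpath:
                    continue
                cand = (dist + 1, refpath + (nxt,))
                if nxt in best and best[nxt] <= cand:
                    continue
                counter += 1
                heapq.heappush(
                    heap,
                    (cand[0], cand[1], counter, nxt, steps + [(transform, direction)]),
                )
        return None

    # -- application -------------------------------------------------------
    @staticmethod
    def compose_affine_path(path: Sequence[PathStep]) -> np.ndarray:
        """Collapse an affine-only chain into a single 4x4 matrix.

        The matrices are composed in traversal order (the first step applies
        first).  A deformation-field step cannot be collapsed — fields
        compose pointwise — and raises :class:`NotComposable`.
        """
        matrix = np.eye(4)
        for transform, direction in path:
            if not isinstance(transform, AffineTransform):
                raise NotComposable("path contains a deformation-field step")
            step = transform.matrix if direction == "forward" else transform.inverse_matrix
            matrix = step @ matrix
        return matrix

    def map_points(self, points, source: str, target: str) -> np.ndarray:
        """Map an (N, 3) array of mm points from one referential to another."""
        path = self.resolve_path(source, target)
        if path is None:
            raise Unreachable(f"no transform path {source!r} -> {target!r}")
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        for transform, direction in path:
            pts = np.atleast_2d(transform.apply(pts, direction))
        return pts

    def map_point(self, point, source: str, target: str) -> np.ndarray:
        """Map one mm point; exact on affine steps, trilinear on field steps."""
        return self.map_points(np.asarray(point, dtype=float)[None, :], source, target)[0]

    def map_mesh(self, mesh: TriangleMesh, source: str, target: str) -> TriangleMesh:
        """Map every vertex of a mesh; the triangle list is unchanged."""
        return TriangleMesh(
            self.map_points(mesh.vertices, source, target), mesh.triangles.copy()
        )
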