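"""Fusion computations: combining loaded objects into derived ones.

Two representative fusion types are implemented headlessly:

* sampling a scalar volume onto the vertices of a surface mesh through an
  arbitrary transform chain (the computation behind texturing a functional
  activation volume onto a gray/white interface mesh);
* intersecting a triangle mesh with a plane, producing the contour
  polylines a 2D slice view would overlay on the cut.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .core_model import TriangleMesh, VolumeGeometry
from .transform_graph import TransformationGraph

#: Endpoint merge tolerance when chaining intersection segments (mm).
CHAIN_TOLERANCE_MM = 1e-9


@dataclass
class VertexTexture:
    """Per-vertex scalar values sampled for a mesh."""

    values: np.ndarray
    background: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()


@dataclass
class PlanePolylines:
    """Intersection of a mesh with a plane: ordered point chains.

    The plane is ``{x : normal . x = offset}`` with a unit normal.  Closed
    loops repeat their first point at the end.
    """

    normal: np.ndarray
    offset: float
    polylines: list[np.ndarray]

    def total_length(self) -> float:
        total = 0.0
        for line in self.polylines:
            total += float(np.linalg.norm(np.diff(line, axis=0), axis=1).sum())
        return total

    def is_closed(self, i: int) -> bool:
        line = self.polylines[i]
        return len(line) > 2 and np.array_equal(line[0], line[-1])


def sample_volume_on_mesh(
    volume: np.ndarray,
    geometry: VolumeGeometry,
    mesh: TriangleMesh,
    tg: Optional[TransformationGraph] = None,
    mesh_ref: Optional[str] = None,
    vol_ref: Optional[str] = None,
    background: float = 0.0,
    interpolation: str = "trilinear",
    time_index: Optional[int] = None,
) -> VertexTexture:
    """Sample a scalar volume at every mesh vertex through a transform chain.

    Vertices are mapped from ``mesh_ref`` to ``vol_ref`` (identity when no
    transformation graph is given), converted to voxel coordinates via the
    volume's geometry, and interpolated (trilinear by default, or
    ``"nearest"``).  Vertices outside the volume grid get ``background``.
    4D volumes need a ``time_index`` selecting one 3D frame.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim == 4:
        if time_index is None:
            raise ValueError("4D volume: a time_index must select one frame")
        volume = volume[..., int(time_index)]
    if volume.shape != geometry.shape:
        raise ValueError(f"volume shape {volume.shape} != geometry shape {geometry.shape}")

    points = mesh.vertices
    if tg is not None and mesh_ref is not None and vol_ref is not None:
        points = tg.map_points(points, mesh_ref, vol_ref)
    vox = np.atleast_2d(geometry.world_to_voxel_coords(points))

    method = {"trilinear": "linear", "nearest": "nearest"}[interpolation]
    axes = tuple(np.arange(s, dtype=float) for s in geometry.shape)
    interp = RegularGridInterpolator(
        axes, volume, method=method, bounds_error=False, fill_value=np.nan
    )
    values = interp(vox)
    values = np.where(np.isnan(values), background, values)
    return VertexTexture(values, background)


def _signed_distances(vertices: np.ndarray, normal: np.ndarray, offset: float):
    return vertices @ normal - offset


def mesh_plane_intersection(
    mesh: TriangleMesh, normal: Sequence[float], offset: float
) -> PlanePolylines:
    """Intersect a triangle mesh with a plane, chaining segments into
    polylines.

    Each triangle crossing the plane contributes one segment; segments
    sharing an endpoint (within 1e-9 mm) are chained, and closed loops are
    closed explicitly.  Vertices lying exactly on the plane count as on the
    positive side, which keeps degenerate cases deterministic.
    """
    normal = np.asarray(normal, dtype=float)
    norm = np.linalg.norm(normal)
    if norm == 0:
        raise ValueError("plane normal cannot be zero")
    normal = normal / norm
    offset = float(offset) / norm

    d = _signed_distances(mesh.vertices, normal, offset)
    positive = d >= 0  # on-plane vertices count as positive side

    segments: list[tuple[np.ndarray, np.ndarray]] = []
    for tri in mesh.triangles:
        signs = positive[tri]
        if signs.all() or not signs.any():
            continue
        pts = []
        for i in range(3):
            a, b = tri[i], tri[(i + 1) % 3]
            if positive[a] == positive[b]:
                continue
            t = d[a] / (d[a] - d[b])
            pts.append(mesh.vertices[a] + t * (mesh.vertices[b] - mesh.vertices[a]))
        if len(pts) == 2 and np.linalg.norm(pts[0] - pts[1]) > 0:
            segments.append((pts[0], pts[1]))

    polylines = _chain_segments(segments)
    return PlanePolylines(normal, offset, polylines)


def _quantize(point: np.ndarray) -> tuple:
    return tuple(np.round(point / CHAIN_TOLERANCE_MM).astype(np.int64).tolist())


def _chain_segments(segments) -> list[np.ndarray]:
    """Chain segments into polylines by shared endpoints; open chains first,
    then closed loops (explicitly closed)."""
    adjacency: dict[tuple, list[int]] = {}
    endpoints = []
    for i, (p, q) in enumerate(segments):
        kp, kq = _quantize(p), _quantize(q)
        endpoints.append((kp, kq))
        adjacency.setdefault(kp, []).append(i)
        adjacency.setdefault(kq, []).append(i)
    point_of = {}
    for (p, q), (kp, kq) in zip(segments, endpoints):
        point_of.setdefault(kp, p)
        point_of.setdefault(kq, q)

    used = [False] * len(segments)

    def walk(start_key: tuple) -> list[tuple]:
        chain = [start_key]
        current = start_key
        while True:
            nxt_seg = None
            for si in adjacency[current]:
                if not used[si]:
                    nxt_seg = si
                    break
            if nxt_seg is None:
                return chain
            used[nxt_seg] = True
            kp, kq = endpoints[nxt_seg]
            current = kq if current == kp else kp
            chain.append(current)

    polylines = []
    # open chains start from degree-1 endpoints (deterministic sorted order)
    for key in sorted(adjacency):
        if len(adjacency[key]) == 1 and not used[adjacency[key][0]]:
            chain = walk(key)
            polylines.append(np.array([point_of[k] for k in chain]))
    # remaining segments form closed loops
    for key in sorted(adjacency):
        if any(not used[si] for si in adjacency[key]):
            chain = walk(key)
            pts = [point_of[k] for k in chain]
            if chain[0] != chain[-1]:
                pts.append(point_of[chain[0]])  # close explicitly
            polylines.append(np.array(pts))
    return polylines
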