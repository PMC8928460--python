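"""Per-structure morphometry: node measurements and per-sulcus aggregation.

Node-level measurements are derived from the fold's voxel representation:
size (volume), surface area, length along the fold's main axis, and depth
statistics along its second principal axis.  True sulcal depth would require
the brain hull, which is not part of the graph model, so the depth axis is
approximated by the voxel cloud's second principal direction; the
approximation is exact for flat, ribbon-like folds.  Cortical thickness and
sulcal opening require the original MRI and are passed through untouched
when already stored on the node.

Aggregation produces long-format ``(subject, label, metric, value)`` records:
one sulcus is the union of the fold nodes sharing its label, so additive
metrics (size, surface_area, length) are summed per label and intensive
metrics (depths, thickness, opening) are size-weighted means.  Population
statistics across subjects are then a plain group-by away.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .core_model import StructureNode, StructuralGraph, VolumeGeometry
from .errors import IdCollision, NoRepresentation
from .nomenclature import Nomenclature

#: Metrics recognised in morphometry tables.
METRIC_REGISTRY = (
    "size",
    "surface_area",
    "length",
    "max_depth",
    "mean_depth",
    "thickness",
    "opening",
)

#: Metrics summed over the fold nodes of one sulcus.
SUMMED_METRICS = ("size", "surface_area", "length")

#: Metrics averaged over fold nodes, weighted by node size.
WEIGHTED_METRICS = ("max_depth", "mean_depth", "thickness", "opening")


class MorphometryTable:
    """Long-format (subject, label, metric, value) measurement records."""

    COLUMNS = ("subject", "label", "metric", "value")

    def __init__(self, rows: Iterable[tuple] = ()):
        rows = list(rows)
        seen = set()
        for subject, label, metric, _value in rows:
            if metric not in METRIC_REGISTRY:
                raise ValueError(f"unknown metric {metric!r}")
            key = (subject, label, metric)
            if key in seen:
                raise IdCollision(f"duplicate morphometry row {key}")
            seen.add(key)
        self.rows = [(s, l, m, float(v)) for s, l, m, v in rows]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=list(self.COLUMNS))

    def value(self, subject: str, label: str, metric: str) -> float:
        for s, l, m, v in self.rows:
            if (s, l, m) == (subject, label, metric):
                return v
        raise KeyError((subject, label, metric))

    def extend(self, other: "MorphometryTable") -> "MorphometryTable":
        return MorphometryTable(self.rows + other.rows)

    def __len__(self):
        return len(self.rows)

    def __eq__(self, other):
        if not isinstance(other, MorphometryTable):
            return NotImplemented
        return sorted(self.rows) == sorted(other.rows)


def _principal_axes(coords: np.ndarray) -> np.ndarray:
    """Principal directions of a point cloud, rows sorted by decreasing
    variance.  Signs fixed so each axis has a non-negative largest component
    (determinism)."""
    centered = coords - coords.mean(axis=0)
    # SVD of the centered cloud; right singular vectors = principal axes.
    _, _, vt = np.linalg.svd(centered, full_matrices=True)
    axes = vt
    for i in range(3):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    return axes


def _voxel_footprint(axis: np.ndarray, geometry: VolumeGeometry) -> float:
    """Width of one voxel projected on a world-space unit direction."""
    cols = geometry.voxel_to_world[:3, :3]
    return float(np.abs(axis @ cols).sum())


def compute_node_measures(
    node: StructureNode, geometry: Optional[VolumeGeometry] = None
) -> dict[str, float]:
    """Fill a fold node's measurement properties from its voxel set.

    Computes ``size`` (mm^3), ``surface_area`` (mm^2, voxel count times mean
    voxel-face area — adequate for one-voxel-thick sheet representations),
    ``length`` (extent along the first principal axis, mm, including the
    voxel footprint), ``max_depth`` and ``mean_depth`` (extent statistics
    along the second principal axis, mm).  ``thickness`` and ``opening`` are
    kept as-is when already present.  The node's ``properties`` map is
    updated in place and returned.
    """
    if node.voxel_rep is None:
        raise NoRepresentation(f"node {node.node_id} has no voxel representation")
    geom = geometry or node.voxel_rep.geometry
    coords = geom.voxel_to_world_coords(node.voxel_rep.array)
    n = len(coords)
    sx, sy, sz = geom.voxel_size
    measures = {
        "size": n * geom.voxel_volume,
        "surface_area": n * (sx * sy + sy * sz + sz * sx) / 3.0,
    }
    axes = _principal_axes(coords)
    proj_main = coords @ axes[0]
    proj_depth = coords @ axes[1]
    measures["length"] = float(np.ptp(proj_main)) + _voxel_footprint(axes[0], geom)
    depth_span = _voxel_footprint(axes[1], geom)
    measures["max_depth"] = float(np.ptp(proj_depth)) + depth_span
    measures["mean_depth"] = float(np.mean(proj_depth - proj_depth.min())) + depth_span / 2.0
    for passthrough in ("thickness", "opening"):
        if passthrough in node.properties:
            measures[passthrough] = node.properties[passthrough]
    node.properties.update(measures)
    return dict(measures)


def aggregate(
    graph: StructuralGraph,
    nomenclature: Optional[Nomenclature] = None,
    recompute: bool = True,
) -> MorphometryTable:
    """Per-label morphometry of one subject's graph.

    Sums additive metrics and size-weights intensive ones over the fold
    nodes sharing each label; unidentified folds are reported under the
    UNKNOWN sentinel label.  Labels without any node do not appear.
    """
    by_label: dict[str, list[StructureNode]] = {}
    for node in graph.nodes.values():
        if recompute and node.voxel_rep is not None:
            compute_node_measures(node)
        by_label.setdefault(node.label, []).append(node)

    rows = []
    for label in sorted(by_label):
        nodes = by_label[label]
        for metric in SUMMED_METRICS:
            vals = [n.properties[metric] for n in nodes if metric in n.properties]
            if vals:
                rows.append((graph.subject_id, label, metric, sum(vals)))
        for metric in WEIGHTED_METRICS:
            pairs = [
                (n.properties[metric], n.properties.get("size", 1.0))
                for n in nodes
                if metric in n.properties
            ]
            if pairs:
                weighted = sum(v * w for v, w in pairs) / sum(w for _, w in pairs)
                rows.append((graph.subject_id, label, metric, weighted))
    return MorphometryTable(rows)


def cohort_table(cohort, nomenclature: Optional[Nomenclature] = None) -> MorphometryTable:
    """Concatenated per-subject aggregates for a whole cohort.

    One row per (subject, label, metric); duplicate subject identifiers
    raise :class:`IdCollision`.
    """
    table = MorphometryTable()
    seen: set[str] = set()
    for subject_id in sorted(cohort.subjects):
        if subject_id in seen:
            raise IdCollision(f"duplicate subject id {subject_id!r}")
        seen.add(subject_id)
        table = table.extend(aggregate(cohort.subjects[subject_id], nomenclature))
    return table
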