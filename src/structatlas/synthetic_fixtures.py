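"""Seeded generator of sulcal-like structural graphs and cohorts.

Real fold graphs come out of an MRI segmentation pipeline; this module
emulates their essential features so every other module is testable without
any acquisition: each fold is a parametric spline ribbon — a deliberately
idealized "negative cast" — swept from a hull-level curve down a depth
direction and rasterized one voxel thick into the volume grid.  Each
nomenclature label gets a stable spatial location and shape template across
subjects (sulci have a roughly stable topography), while per-subject
jitter and stochastic variability events reproduce the classic sulcal
configurations: a single long fold; interruption into several pieces,
optionally with parallel overlap; small side branches; a short plus a long
branch at a shifted position; and a shortened fold with a missing part.
Junction edges are added where generated folds touch, proximity edges for
pairs within a distance threshold.

Every generated graph carries a ground-truth manifest (node→label and an
event log), so label selections and consistency checks can be verified
against what was injected.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Union

import numpy as np
from scipy.spatial import cKDTree

from .cohort import Cohort
from .core_model import (
    EdgeKind,
    Hemisphere,
    StructureEdge,
    StructureNode,
    StructuralGraph,
    VolumeGeometry,
    VoxelSurfaceSet,
)
from .errors import DegenerateInput
from .nomenclature import Nomenclature, NomenclatureEntry
from .transform_graph import AffineTransform

#: Arc-length sampling step when rasterizing ribbons, in voxel units.
RASTER_STEP_VOXELS = 0.4

#: Default proximity-edge distance threshold (mm).
PROXIMITY_THRESHOLD_MM = 3.0

_LOBES = (
    ("frontal", (255, 80, 80)),
    ("parietal", (80, 160, 255)),
    ("temporal", (80, 220, 120)),
    ("occipital", (250, 200, 60)),
    ("insula", (200, 110, 240)),
    ("limbic", (150, 150, 150)),
)


@dataclass(frozen=True)
class VariabilityProfile:
    """Per-label probabilities of the sulcal variability events, plus the
    geometric jitter applied to each subject's fold shapes (mm std)."""

    interruption: float = 0.25
    parallel_overlap: float = 0.3  # drawn only when an interruption occurred
    small_branch: float = 0.2
    long_branch: float = 0.1
    missing_part: float = 0.1
    dropout: float = 0.0  # label entirely absent from a subject
    jitter_std: float = 0.5

    def __post_init__(self):
        for name in (
            "interruption",
            "parallel_overlap",
            "small_branch",
            "long_branch",
            "missing_part",
            "dropout",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} probability must be in [0, 1], got {p}")

    def expected_folds_per_label(self) -> float:
        """Expected fold-node count one label contributes to a subject."""
        extra = (
            self.interruption * 1.0
            + self.small_branch * 1.5
            + self.long_branch * 2.0
        )
        return (1.0 + extra) * (1.0 - self.dropout)


@dataclass
class GeneratorConfig:
    """Study conditions for synthetic cohorts.

    Defaults emulate the scale of real sulcal data: about 300 folds per
    hemisphere on a 128^3 grid at 1 mm isotropic resolution.
    """

    seed: int = 0
    n_subjects: int = 1
    folds_per_subject: int = 300
    volume_shape: tuple = (128, 128, 128)
    voxel_size: tuple = (1.0, 1.0, 1.0)
    label_set: Optional[Nomenclature] = None
    variability: Union[VariabilityProfile, Mapping[str, VariabilityProfile]] = field(
        default_factory=VariabilityProfile
    )
    proximity_mm: float = PROXIMITY_THRESHOLD_MM

    def __post_init__(self):
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")

    def default_profile(self) -> VariabilityProfile:
        if isinstance(self.variability, VariabilityProfile):
            return self.variability
        return self.variability.get("*", VariabilityProfile())

    def profile_for(self, label: str) -> VariabilityProfile:
        if isinstance(self.variability, VariabilityProfile):
            return self.variability
        return self.variability.get(label, self.default_profile())

    def geometry(self) -> VolumeGeometry:
        return VolumeGeometry(self.volume_shape, self.voxel_size)

    def nomenclature(self) -> Nomenclature:
        if self.label_set is not None:
            return self.label_set
        n_labels = max(
            1,
            round(self.folds_per_subject / self.default_profile().expected_folds_per_label()),
        )
        return default_nomenclature(n_labels)


@dataclass
class GroundTruthManifest:
    """What the generator actually injected, for oracle checks."""

    #: subject_id -> {node_id: true label}
    labels: dict[str, dict[int, str]] = field(default_factory=dict)
    #: one record per injected event: {"subject", "label", "event"}
    events: list[dict] = field(default_factory=list)

    def events_for(self, event: str) -> set[tuple[str, str]]:
        return {(e["subject"], e["label"]) for e in self.events if e["event"] == event}


def default_nomenclature(n_labels: int) -> Nomenclature:
    """Hierarchical nomenclature with ``n_labels`` leaf sulcus names grouped
    under colored lobe entries."""
    lobes = []
    per_lobe = -(-n_labels // len(_LOBES))
    made = 0
    for lobe_name, color in _LOBES:
        children = []
        while made < n_labels and len(children) < per_lobe:
            made += 1
            children.append(NomenclatureEntry(f"S.{lobe_name[:3].capitalize()}.{len(children) + 1}"))
        if children:
            lobes.append(NomenclatureEntry(lobe_name, color=color, children=children))
    root = NomenclatureEntry("brain", children=lobes)
    return Nomenclature(root)


# ---------------------------------------------------------------------------
# fold rasterization
# ---------------------------------------------------------------------------

def _resample_curve(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at constant arc-length step (keeps both ends out
    of the last partial cell: samples live in [0, L) )."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total <= step:
        raise DegenerateInput(f"curve length {total:.3g} mm below one raster step")
    # midpoint sampling: symmetric w.r.t. sweep direction, and a ribbon of
    # area A rasterizes to about A / voxel-face-area cells
    t = np.arange(step / 2.0, total, step)
    return np.column_stack([np.interp(t, arclen, points[:, a]) for a in range(3)])


def generate_fold(
    template_curve,
    depth: float,
    jitter: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    geometry: Optional[VolumeGeometry] = None,
    depth_direction=(0.0, 0.0, -1.0),
) -> VoxelSurfaceSet:
    """Rasterize one fold: a ribbon swept from a curve along a depth
    direction, one voxel thick along its normal.

    ``template_curve`` is a polyline of world-mm control points; ``depth``
    the sweep extent in mm.  ``jitter`` displaces the control points with
    Gaussian noise (mm std) before rasterization, keeping the ribbon smooth.
    Raises :class:`DegenerateInput` on non-positive depth or a collapsed
    curve.  Voxels falling outside the grid are dropped and, should that
    disconnect the ribbon, only the largest 26-connected piece is kept.
    """
    if depth <= 0:
        raise DegenerateInput(f"fold depth must be > 0 mm, got {depth}")
    geometry = geometry or VolumeGeometry((128, 128, 128), (1.0, 1.0, 1.0))
    curve = np.atleast_2d(np.asarray(template_curve, dtype=float))
    if curve.shape[0] < 2 or curve.shape[1] != 3:
        raise DegenerateInput("template curve needs at least two 3D points")
    if jitter > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        curve = curve + rng.normal(0.0, jitter, size=curve.shape)

    d = np.asarray(depth_direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise DegenerateInput("depth direction cannot be zero")
    d = d / norm

    step = RASTER_STEP_VOXELS * min(geometry.voxel_size)
    line = _resample_curve(curve, step)
    depths = np.arange(step / 2.0, depth, step)
    sheet = line[None, :, :] + depths[:, None, None] * d  # (S, T, 3)
    vox = np.floor(geometry.world_to_voxel_coords(sheet.reshape(-1, 3))).astype(np.int64)
    shape = np.array(geometry.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    vox = vox[inside]
    if len(vox) == 0:
        raise DegenerateInput("fold rasterizes entirely outside the volume grid")
    voxset = VoxelSurfaceSet(map(tuple, vox), geometry)
    comps = voxset.connected_components()
    if len(comps) > 1:  # clipped at the border
        voxset = VoxelSurfaceSet(comps[0], geometry)
    return voxset


# ---------------------------------------------------------------------------
# per-label shape templates (stable across subjects)
# ---------------------------------------------------------------------------

def _label_rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([seed % (2**31), zlib.crc32(label.encode())])


def _lattice_centers(n: int, shape, voxel_size, margin_mm: float = 14.0) -> np.ndarray:
    """Evenly spaced anchor points for n labels inside the volume."""
    extent = np.array(shape) * np.array(voxel_size)
    per_axis = int(np.ceil(n ** (1.0 / 3.0)))
    axes = [
        np.linspace(margin_mm, e - margin_mm, per_axis) if per_axis > 1 else [e / 2.0]
        for e in extent
    ]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    return grid[:n]


@dataclass
class _LabelTemplate:
    center: np.ndarray
    direction: np.ndarray  # unit, roughly horizontal
    lateral: np.ndarray  # unit, perpendicular to direction and depth
    depth_direction: np.ndarray  # unit, roughly -z
    length: float
    depth: float
    wiggle: float  # curvature amplitude, mm


def _make_template(rng: np.random.Generator, center: np.ndarray) -> _LabelTemplate:
    azimuth = rng.uniform(0.0, np.pi)
    elevation = rng.uniform(-0.15, 0.15)
    direction = np.array(
        [np.cos(azimuth) * np.cos(elevation), np.sin(azimuth) * np.cos(elevation), np.sin(elevation)]
    )
    tilt = rng.uniform(-0.12, 0.12, size=2)
    depth_direction = np.array([tilt[0], tilt[1], -1.0])
    depth_direction /= np.linalg.norm(depth_direction)
    lateral = np.cross(direction, depth_direction)
    lateral /= np.linalg.norm(lateral)
    return _LabelTemplate(
        center=center + rng.uniform(-2.0, 2.0, size=3),
        direction=direction,
        lateral=lateral,
        depth_direction=depth_direction,
        length=rng.uniform(12.0, 18.0),
        depth=rng.uniform(6.0, 10.0),
        wiggle=rng.uniform(0.5, 2.0),
    )


def _template_curve(tpl: _LabelTemplate, t0: float = 0.0, t1: float = 1.0) -> np.ndarray:
    """Control polyline of the template over parameter range [t0, t1]."""
    t = np.linspace(t0, t1, max(2, int(np.ceil((t1 - t0) * 8)) + 2))
    along = (t - 0.5) * tpl.length
    bend = tpl.wiggle * np.sin(np.pi * t)
    return tpl.center + along[:, None] * tpl.direction + bend[:, None] * tpl.lateral


def _clamp_inside(curve: np.ndarray, tpl: _LabelTemplate, geometry: VolumeGeometry) -> np.ndarray:
    """Shift a curve so the swept ribbon's bounding box fits in the grid."""
    extent = np.array(geometry.shape) * np.array(geometry.voxel_size)
    corners = np.vstack([curve, curve + tpl.depth * tpl.depth_direction])
    lo, hi = corners.min(axis=0), corners.max(axis=0)
    shift = np.maximum(1.0 - lo, 0.0) + np.minimum(extent - 1.0 - hi, 0.0)
    return curve + shift


# ---------------------------------------------------------------------------
# subject and cohort generation
# ---------------------------------------------------------------------------

def _subject_curves(
    config: GeneratorConfig,
    tpl: _LabelTemplate,
    profile: VariabilityProfile,
    rng: np.random.Generator,
) -> tuple[list[np.ndarray], list[str]]:
    """Draw this subject's variability configuration for one label; returns
    the fold curves to rasterize and the injected event names."""
    events: list[str] = []
    if rng.random() < profile.dropout:
        return [], ["dropout"]

    t0, t1 = 0.0, 1.0
    if rng.random() < profile.missing_part:
        events.append("missing_part")
        t1 = rng.uniform(0.55, 0.7)

    curves: list[np.ndarray] = []
    if rng.random() < profile.interruption:
        events.append("interruption")
        cut = rng.uniform(0.4, 0.6) * (t1 - t0) + t0
        gap = rng.uniform(0.04, 0.06) * (t1 - t0)
        first = _template_curve(tpl, t0, cut - gap)
        if rng.random() < profile.parallel_overlap:
            events.append("parallel_overlap")
            overlap = rng.uniform(0.1, 0.2) * (t1 - t0)
            second = _template_curve(tpl, max(t0, cut - overlap), t1)
            second = second + rng.uniform(2.0, 3.5) * tpl.lateral
        else:
            second = _template_curve(tpl, cut + gap, t1)
        curves += [first, second]
    else:
        curves.append(_template_curve(tpl, t0, t1))

    if rng.random() < profile.small_branch:
        events.append("small_branch")
        for _ in range(rng.integers(1, 3)):
            curves.append(_branch_curve(tpl, rng, rng.uniform(0.3, 0.45)))
    if rng.random() < profile.long_branch:
        events.append("long_branch")
        shift = rng.uniform(2.0, 4.0) * tpl.lateral
        curves.append(_branch_curve(tpl, rng, 0.25) + shift)
        curves.append(_branch_curve(tpl, rng, rng.uniform(0.6, 0.75)) + shift)
    return curves, events


def _branch_curve(
    tpl: _LabelTemplate, rng: np.random.Generator, rel_length: float
) -> np.ndarray:
    """A side branch: starts on the main curve, heads off at an angle."""
    t_start = rng.uniform(0.2, 0.8)
    start = _template_curve(tpl, t_start, t_start + 1e-3)[0]
    angle = rng.choice([-1.0, 1.0]) * rng.uniform(0.6, 1.2)
    direction = np.cos(angle) * tpl.direction + np.sin(angle) * tpl.lateral
    length = rel_length * tpl.length
    t = np.linspace(0.0, 1.0, 5)
    return start + (t[:, None] * length) * direction


def derive_edges(
    graph: StructuralGraph, proximity_mm: float = PROXIMITY_THRESHOLD_MM
) -> StructuralGraph:
    """Add topographic edges: junctions where voxel sets are 26-adjacent,
    proximity edges for pairs within ``proximity_mm`` (world distance).

    Existing edges are replaced.  Candidate pairs are pruned with bounding
    boxes before exact nearest-pair distances are computed.
    """
    graph.edges.clear()
    ids = sorted(nid for nid, n in graph.nodes.items() if n.voxel_rep is not None)
    if len(ids) < 2:
        return graph
    reps = {nid: graph.nodes[nid].voxel_rep for nid in ids}
    world = {nid: reps[nid].world_coords() for nid in ids}
    boxes = np.array([[world[nid].min(axis=0), world[nid].max(axis=0)] for nid in ids])
    trees = {nid: cKDTree(world[nid]) for nid in ids}
    voxsets = {nid: reps[nid].voxels for nid in ids}

    lo, hi = boxes[:, 0, :], boxes[:, 1, :]
    gap = np.maximum(lo[None, :, :] - hi[:, None, :], lo[:, None, :] - hi[None, :, :])
    box_dist = np.linalg.norm(np.maximum(gap, 0.0), axis=-1)

    offsets = np.array(
        [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    )
    eid = 0
    for ai in range(len(ids)):
        for bi in range(ai + 1, len(ids)):
            if box_dist[ai, bi] > proximity_mm:
                continue
            a, b = ids[ai], ids[bi]
            small, large = (a, b) if len(reps[a]) <= len(reps[b]) else (b, a)
            dmin = float(trees[large].query(world[small])[0].min())
            if dmin > proximity_mm:
                continue
            # 26-adjacency implies centre distance <= sqrt(3) * voxel size
            touch_reach = float(np.linalg.norm(graph.geometry.voxel_size)) + 1e-9
            touching = dmin <= touch_reach and any(
                tuple(v) in voxsets[large]
                for v in (reps[small].array[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
            )
            kind = EdgeKind.JUNCTION if touching else EdgeKind.PROXIMITY
            graph.add_edge(
                StructureEdge(eid, kind, (a, b), {"min_distance_mm": dmin})
            )
            eid += 1
    return graph


def generate_subject(
    config: GeneratorConfig,
    rng: np.random.Generator,
    subject_id: str = "sub-000",
) -> tuple[StructuralGraph, dict[int, str], list[dict]]:
    """Generate one subject's fold graph.

    Label shape templates are stable across subjects (derived from the
    config seed and the label name); the per-subject ``rng`` drives jitter
    and variability events.  Returns the graph, the node→label ground
    truth, and the injected event records.
    """
    geometry = config.geometry()
    nom = config.nomenclature()
    graph = StructuralGraph(subject_id, Hemisphere.LEFT, f"native:{subject_id}")
    truth: dict[int, str] = {}
    events: list[dict] = []

    labels = sorted(nom.leaf_names())
    centers = _lattice_centers(len(labels), config.volume_shape, config.voxel_size)
    order = _label_rng(config.seed, "__placement__").permutation(len(labels))

    node_id = 0
    for i, label in enumerate(labels):
        tpl = _make_template(_label_rng(config.seed, label), centers[order[i]])
        profile = config.profile_for(label)
        curves, label_events = _subject_curves(config, tpl, profile, rng)
        for ev in label_events:
            events.append({"subject": subject_id, "label": label, "event": ev})
        for curve in curves:
            curve = _clamp_inside(curve, tpl, geometry)
            fold = generate_fold(
                curve,
                tpl.depth,
                jitter=profile.jitter_std,
                rng=rng,
                geometry=geometry,
                depth_direction=tpl.depth_direction,
            )
            graph.add_node(StructureNode(node_id, label, fold))
            truth[node_id] = label
            node_id += 1
    derive_edges(graph, config.proximity_mm)
    return graph, truth, events


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, GroundTruthManifest]:
    """Generate ``config.n_subjects`` independent subjects from one seeded
    stream (subject substreams are derived from seed and subject index, so
    any subject can be regenerated alone) plus rigid native→common affines.
    """
    nom = config.nomenclature()
    cohort = Cohort(shared_nomenclature=nom)
    manifest = GroundTruthManifest()
    for i in range(config.n_subjects):
        subject_id = f"sub-{i:03d}"
        rng = np.random.default_rng([config.seed % (2**31), i])
        graph, truth, events = generate_subject(config, rng, subject_id)
        cohort.add_subject(graph, to_common=_rigid_to_common(graph.referential_id, rng))
        manifest.labels[subject_id] = truth
        manifest.events.extend(events)
    return cohort, manifest


def _rigid_to_common(source_ref: str, rng: np.random.Generator) -> AffineTransform:
    """Small rigid alignment of a native space into the common space."""
    angles = rng.uniform(-0.05, 0.05, size=3)
    translation = rng.uniform(-3.0, 3.0, size=3)
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rot_x = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    rot_y = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rot_z = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    matrix = np.eye(4)
    matrix[:3, :3] = rot_z @ rot_y @ rot_x
    matrix[:3, 3] = translation
    return AffineTransform(source_ref, "common", matrix)
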