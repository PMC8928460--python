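# Methods

`structatlas` is a headless library for *structural* brain atlases: instead
of warping every subject onto a template ("iconic" correspondence), each
subject keeps its native geometry and inter-subject correspondence is
carried by annotations from a shared hierarchical nomenclature.  This note
documents the models, the numerical choices, and what the synthetic data do
and do not establish.

## The structural-graph model

One subject (typically one hemisphere) is a graph whose nodes are elementary
cortical folds and whose edges are topographic relations between them.  A
fold is represented by the voxel set of the "negative cast" of the sulcal
cerebrospinal-fluid space — a one-voxel-thick sheet extending from the brain
hull to the fundus — and optionally by a triangle mesh.  Edges are of two
kinds: `junction` (the folds touch) and `proximity` (they lie close without
touching).  All voxel sets of one graph share a single sampling geometry
(shape, voxel size, and a 4×4 voxel→world matrix mapping 0-based indices to
millimetres, voxel-centre convention).

Numerical/representation choices:

* **Connectivity is the 26-neighbourhood.**  Fold casts are thin sheets;
  vertex connectivity is the most permissive choice and keeps rasterized
  one-voxel sheets in one piece.
* **The unidentified label is the literal string `unknown`**, one canonical
  spelling so round-trips are unambiguous.
* **Node properties are scalar reals only**; anything vector-valued is
  flattened to named scalars.
* `validate()` reports violations (dangling edges, disconnected casts,
  geometry mismatches, labels outside the nomenclature) rather than raising,
  so malformed data can be loaded, inspected and repaired.

## Nomenclatures

A nomenclature is a tree of structure names with optional 8-bit RGB display
colors.  Names are unique tree-wide (label→entry resolution must never be
ambiguous).  Color resolution walks toward the root and returns the nearest
colored ancestor, or nothing; `subtree_labels` expands a non-leaf name into
all names below it, which is how "select the inferior frontal sulcus" can
select its several sub-entities at once.

## The transformation graph

Each piece of data lives in its own *referential*.  Transforms join
referentials in a graph with no distinguished central space:

* **Affine transforms** (4×4 homogeneous, mm→mm) are traversed in either
  direction; the inverse matrix is computed on demand.
* **Deformation fields** are dense non-linear maps sampled on a source-space
  grid.  They are stored as *absolute target-space coordinates* per source
  voxel (not displacements — this removes any ambiguity about which space a
  displacement lives in; a reader option converts displacement-convention
  files on load).  Field edges are strictly directed: such warps need not be
  invertible anywhere, so the inverse is never synthesized.  Users who need
  both directions register both fields.
* **Resolution** returns the chain with the fewest edges; among equally
  short chains the lexicographically smallest sequence of referential ids
  wins, so resolution is deterministic.  Hop count rather than any trust
  weighting is this package's own policy.
* **Application**: affine steps are exact; field steps sample the field by
  trilinear interpolation at the current point (converted to field voxel
  coordinates through the field's geometry).  Trilinear interpolation is
  exact on affine-valued fields, which is the basis of the field tests.
  Points outside the sampled support raise `OutOfField` rather than
  extrapolate.  Affine-only chains can be collapsed to one matrix; chains
  containing a field step cannot (fields compose pointwise only).

## Editing

Labeling follows the copy/paste workflow of atlas annotation: a label is
picked from a node (in any subject) into a clipboard with provenance and
pasted onto selected nodes, validated against the nomenclature.

**Fold splitting** divides one fold node in two along a cutting line through
one or more user points.  The full procedure is this package's own design
(the user gesture only fixes the endpoints and the outcome):

1. each seed point snaps to its nearest voxel of the fold; if no seed lies
   within 2 voxels of the set the cut is rejected (`SeedOffStructure`);
2. consecutive snapped seeds are joined by shortest 26-connected paths
   *inside* the set, preferring axis-aligned steps among equally short
   paths (diagonal staircases do not separate a voxel sheet);
3. the spine is extended at both ends along the fold's depth direction until
   it leaves the set.  The depth direction is the **second** principal axis
   of the voxel cloud — the same definition morphometry uses (the first
   axis is the fold's length; extending along it would grow T-shaped spines
   and over-segment);
4. removing the spine must leave exactly two 26-connected components
   (`CutIneffective` / `AmbiguousCut` otherwise); they become the children;
5. spine voxels are handed to the nearer component (ties to the larger one),
   with a repair pass that moves any stranded spine fragment to the other
   child, so the children exactly partition the parent;
6. former edges re-home to the child with the smaller minimum voxel-pair
   distance to the former neighbour; a junction edge joins the children;
   children inherit the parent label (relabeling happens afterwards with
   copy/paste); parent meshes are dropped — they no longer describe either
   child and must be re-meshed downstream.

`merge_nodes` is the inverse (kept deliberately simple, as an undo): union
of the voxel sets, first node's id and label, edges re-homed, the
inter-pair edge removed.

## Morphometry

Per-node measurements from the voxel cast, with principal axes computed by
SVD of the centred voxel-centre cloud (axis signs fixed deterministically):

| metric | definition | unit |
|---|---|---|
| `size` | voxel count × voxel volume | mm³ |
| `surface_area` | voxel count × mean voxel-face area | mm² |
| `length` | extent along the 1st principal axis + voxel footprint | mm |
| `max_depth` | extent along the 2nd principal axis + voxel footprint | mm |
| `mean_depth` | mean offset from the shallowest point + half footprint | mm |
| `thickness`, `opening` | passthrough when present | mm |

The voxel footprint (the width of one voxel projected on an axis) makes the
measures agree with the physical dimensions of axis-aligned slabs: a
20 × 10 × 1 mm ribbon at 1 mm isotropic measures length 20, max depth 10.
The depth axis is an **approximation**: true sulcal depth is measured from
the brain hull, which the graph model does not carry; the approximation is
exact for flat ribbon-like folds and degrades with strong curvature.
Thickness and sulcal opening require the original MRI and are only carried
through, never estimated here.

Aggregation treats a sulcus as the union of the fold nodes sharing its
label: `size`, `surface_area` and `length` are summed; depth metrics (and
thickness/opening) are size-weighted means.  Tables are long-format
`(subject, label, metric, value)` rows — fixed CSV column order
`subject,label,metric,value` — so population statistics are a group-by in
any stats tool; no statistical testing is done here.

## Fusion computations

Two representative fusion types are implemented:

* **Volume-on-mesh sampling**: vertices are mapped through the transform
  graph into the volume's referential, converted to voxel coordinates, and
  interpolated (trilinear by default; nearest-neighbour available — the
  choice is exposed as a flag).  Out-of-grid vertices receive a background
  value.  4D volumes require an explicit time index; no temporal
  interpolation.
* **Mesh/plane intersection**: each triangle crossing the plane contributes
  one segment; vertices exactly on the plane count as positive side
  (deterministic degenerate handling); segments are chained into polylines
  by endpoint coincidence within 1e-9 mm, and closed loops are closed
  explicitly by repeating the first point.

## Cohorts

A cohort maps subject ids to graphs sharing one nomenclature.  Alignment to
a common display space is affine-only and optional — the point of the
structural approach is precisely not to warp individual shapes.
`select_by_label` expands non-leaf names through the nomenclature subtree
and returns per-subject node selections.  `consistency_report` counts, per
label, the subjects containing it, flags labels missing from more than a
threshold fraction of subjects (default 0.2) and labels used but absent
from the nomenclature; the `unknown` sentinel is never flagged.  Pagination
is lexicographic and deterministic.

## Synthetic data generator

The generator emulates what matters for testing this toolkit, not cortical
anatomy.  Each fold is a parametric ribbon: a gently curved hull-level
curve swept ~6–10 mm along a near-vertical depth direction and rasterized
one voxel thick (arc-length step 0.4 voxel, midpoint sampling, so a ribbon
of area A rasterizes to ≈ A / face-area voxels).  Each label has a *stable*
template (position on a jittered lattice, orientation, length 12–18 mm,
depth, curvature) derived from the cohort seed and the label name, so the
same sulcus lands in roughly the same place in every subject; per-subject
Gaussian jitter (default 0.5 mm std) individualizes shapes.

Per subject and label, variability events are drawn independently:
interruption into two pieces (default p = 0.25), parallel overlap of the
second piece (p = 0.3, given an interruption), small side branches
(p = 0.2), a short plus a long branch at a shifted position (p = 0.1), a
missing part truncating the fold (p = 0.1), and optional whole-label
dropout (default 0).  Defaults are chosen so a default-sized nomenclature
yields about 300 folds per subject — the typical per-hemisphere count — on
a 128³, 1 mm isotropic grid; cohorts scale to the 60–80 subjects of a
working atlas.  Junction edges are derived where voxel sets are
26-adjacent, proximity edges within 3 mm, with bounding-box pruning before
exact nearest-pair distances.

Every run records a ground-truth manifest (node→label plus an event log),
which is the oracle for selection and consistency tests.  Subject
substreams are derived from (seed, subject index), so any subject can be
regenerated independently.

What passing these tests does **not** show: the generator's ribbons are far
smoother and better separated than real fold casts, label placement is
lattice-like rather than anatomical, and segmentation noise, contact
ambiguities and genuinely doubtful annotations are absent.  Results on real
Morphologist-style graphs will be noisier, particularly for the depth
approximation and for split cuts on strongly curved folds.

## File formats

All structured formats are fresh JSON dialects (`.sgraph.json`,
`.nom.json`, transform and cohort manifests) with a recorded format
version; compatibility with any legacy graph format is explicitly not
claimed.  Writers sort keys and rely on Python's shortest round-trip float
representation, so serialization is byte-deterministic and numerically
exact.  Volumes and deformation fields are NIfTI-1 (fields: 4D with a
3-length last axis); the qform/sform is honoured as the voxel→world map and
files with neither are rejected rather than silently defaulted.  Meshes are
OBJ or GIFTI; textures GIFTI or CSV.  Morphometry CSVs are read back with
round-trip float parsing so read(write(x)) is exact.

## Problem sizes used in the test suite

The default test run exercises: 100 random transformation graphs against
exhaustive path enumeration; 1000-point deformation-field checks; 50
random fold splits; ten 300-fold subjects for morphometry oracles; a
100-subject cohort for event-frequency statistics (binomial 3-SE band);
20 serialization seeds; and one 60-subject, ~300-fold cohort end to end.
These sizes match the package's target working scale while keeping the
suite fast enough to run on every change.
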