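# structatlas

A headless Python toolkit for **structural brain atlases** — collections of
individually annotated subjects sharing a common nomenclature, as opposed to
a single averaged map.

The mainstream way to compare brains is "iconic": warp every subject onto a
template with dense deformation fields.  Cortical folding breaks that
assumption — sulci vary enormously in size, shape and even topology (a
sulcus may be interrupted, duplicated in parallel, carry extra branches, or
be partly missing), so no architecturally faithful point-to-point mapping
exists.  The **structural** alternative extracts discrete structures from
each subject (elementary cortical folds, each a voxel-set "negative cast"
of the sulcal CSF space), embeds them in a graph with their topographic
relations, and matches subjects by *naming* structures from a shared
hierarchical nomenclature while every subject keeps its native coordinate
system.

`structatlas` implements the computational side of building, editing and
exploiting such atlases, with no rendering involved:

* **`core_model`** — structural graphs: fold nodes (voxel casts and/or
  meshes, measurement properties), junction/proximity edges, integrity
  validation.
* **`nomenclature`** — hierarchical structure names with inheritable RGB
  colors, subtree queries.
* **`transform_graph`** — decentralized coordinate systems: referentials
  joined by affine transforms (bidirectional) and deformation fields
  (directed, trilinear), fewest-edges chain resolution and on-the-fly
  composition.  For a chain of affines, a point x maps as
  x ↦ M_k ⋯ M_2 M_1 x.
* **`editing`** — label copy/paste across subjects; splitting a fold along
  a cutting line through selected points, with exact voxel partition and
  graph-topology update; merge as the inverse.
* **`morphometry`** — per-fold size/surface/length/depth measures and
  per-sulcus, per-subject long-format tables for population statistics.
* **`fusion_sampling`** — sampling a scalar volume onto mesh vertices
  through a transform chain; mesh/plane intersection polylines.
* **`cohort`** — multi-subject navigation as computation: select-by-name in
  every subject, annotation consistency audits, pagination.
* **`synthetic_fixtures`** — a seeded generator of sulcal-like graphs and
  cohorts (interruptions, parallel overlaps, branches, missing parts) with
  ground-truth manifests, at the realistic scale of ~300 folds per
  hemisphere and 60+ subjects per atlas.
* **`io`** — deterministic round-trip formats: `.sgraph.json` graphs,
  `.nom.json` nomenclatures, plain-text 4×4 affines, transform/cohort
  manifests, NIfTI volumes and deformation fields, OBJ/GIFTI meshes,
  GIFTI/CSV textures, morphometry CSV.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

```python
import structatlas as sa

# a small synthetic atlas: 3 subjects, 4 sulcus labels, seeded
config = sa.GeneratorConfig(seed=42, n_subjects=3,
                            label_set=sa.default_nomenclature(4))
cohort, manifest = sa.generate_cohort(config)

graph = cohort.subjects["sub-000"]
print("folds:", len(graph), "edges:", len(graph.edges))

table = sa.cohort_table(cohort, cohort.shared_nomenclature)
frame = table.to_frame()
print(frame[frame.metric == "size"].groupby("label").value.mean().round(1))

print(sa.select_by_label(cohort, {"S.Fro.1"}))
print(sa.consistency_report(cohort).to_text())
```

prints

```
folds: 7 edges: 3
label
S.Fro.1    286.0
S.Occ.1    247.3
S.Par.1    230.0
S.Tem.1    192.7
Name: value, dtype: float64
{'sub-000': {0, 1, 2}, 'sub-001': {0}, 'sub-002': {0, 1, 2}}
consistency report over 3 subject(s)
labels used: 4
  no inconsistency found
```

Subject `sub-000` carries 7 fold nodes for 4 sulci (the frontal and
occipital sulci drew variability events and are made of several folds —
exactly why per-sulcus statistics aggregate over labels, not nodes).  The
group-by gives the mean sulcal volume (mm³) per label across subjects.
`select_by_label` finds the same named sulcus in every subject — three
folds in `sub-000`, one in `sub-001` — and the consistency report confirms
every label occurs in every subject.

The same operations are available from the shell:

```sh
structatlas generate --seed 42 --subjects 3 --out atlas/
structatlas morphometry --cohort atlas/ --out table.csv
structatlas consistency --cohort atlas/ --json
structatlas split --graph atlas/sub-000.sgraph.json --node 2 --points 34,61,57
structatlas slice --mesh cortex.obj --normal 0,0,1 --offset 28.5 --out section.json
```

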