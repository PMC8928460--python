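"""Multi-subject structural-atlas navigation, as computation.

A cohort is a set of annotated subject graphs sharing one nomenclature —
a structural atlas.  Each subject stays in its own native coordinate
system; optional affine transforms to a common space provide a shared
orientation without warping anyone's shape.  The operations here are the
computational side of atlas browsing: select the same named structures in
every subject, check the annotations for inconsistencies, page through the
subject list.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Optional

from .core_model import StructuralGraph, UNKNOWN_LABEL
from .errors import IdCollision, LabelNotInNomenclature, NotFound
from .nomenclature import Nomenclature
from .transform_graph import AffineTransform

#: Flag labels absent from more than this fraction of subjects.
DEFAULT_ABSENCE_THRESHOLD = 0.2


@dataclass
class Cohort:
    """Subjects of a structural atlas, keyed by subject id."""

    subjects: dict[str, StructuralGraph] = dataclass_field(default_factory=dict)
    shared_nomenclature: Optional[Nomenclature] = None
    to_common: dict[str, AffineTransform] = dataclass_field(default_factory=dict)

    def add_subject(
        self, graph: StructuralGraph, to_common: Optional[AffineTransform] = None
    ) -> "Cohort":
        if graph.subject_id in self.subjects:
            raise IdCollision(f"duplicate subject id {graph.subject_id!r}")
        if to_common is not None and to_common.source != graph.referential_id:
            raise ValueError(
                f"to_common source {to_common.source!r} does not match the "
                f"graph referential {graph.referential_id!r}"
            )
        self.subjects[graph.subject_id] = graph
        if to_common is not None:
            self.to_common[graph.subject_id] = to_common
        return self

    def __len__(self):
        return len(self.subjects)


def select_by_label(cohort: Cohort, names) -> dict[str, set[int]]:
    """Select, in every subject, the nodes carrying any of the given names.

    Non-leaf nomenclature names select their whole subtree (a sulcus made
    up of several sub-entities selects all of them).  Subjects containing
    none of the names map to an empty set.
    """
    nom = cohort.shared_nomenclature
    expanded: set[str] = set()
    for name in names:
        if nom is not None:
            if not nom.contains(name):
                raise LabelNotInNomenclature(f"name {name!r} not in nomenclature")
            expanded |= nom.subtree_labels(name)
        else:
            expanded.add(name)
    return {
        subject_id: {n.node_id for n in graph.nodes.values() if n.label in expanded}
        for subject_id, graph in cohort.subjects.items()
    }


@dataclass
class ConsistencyReport:
    """Annotation consistency across the subjects of a cohort."""

    n_subjects: int
    #: label -> number of subjects containing it
    subject_counts: dict[str, int]
    #: label -> {subject_id: node count}
    node_counts: dict[str, dict[str, int]]
    #: labels missing from more than the threshold fraction of subjects
    flagged_missing: dict[str, list[str]]
    #: labels used in graphs but absent from the nomenclature
    not_in_nomenclature: list[str]
    absence_threshold: float

    @property
    def flags(self) -> set[str]:
        return set(self.flagged_missing) | set(self.not_in_nomenclature)

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "absence_threshold": self.absence_threshold,
            "subject_counts": dict(sorted(self.subject_counts.items())),
            "node_counts": {
                k: dict(sorted(v.items())) for k, v in sorted(self.node_counts.items())
            },
            "flagged_missing": {
                k: sorted(v) for k, v in sorted(self.flagged_missing.items())
            },
            "not_in_nomenclature": sorted(self.not_in_nomenclature),
        }

    def to_text(self) -> str:
        lines = [
            f"consistency report over {self.n_subjects} subject(s)",
            f"labels used: {len(self.subject_counts)}",
        ]
        for label, missing in sorted(self.flagged_missing.items()):
            lines.append(
                f"  FLAG {label!r}: present in {self.subject_counts[label]}"
                f"/{self.n_subjects} subjects (missing: {', '.join(sorted(missing))})"
            )
        for label in sorted(self.not_in_nomenclature):
            lines.append(f"  FLAG {label!r}: not in the shared nomenclature")
        if not self.flags:
            lines.append("  no inconsistency found")
        return "\n".join(lines)


def consistency_report(
    cohort: Cohort, absence_threshold: float = DEFAULT_ABSENCE_THRESHOLD
) -> ConsistencyReport:
    """Cross-subject annotation audit.

    Counts, per label, the subjects containing it and their node counts;
    flags labels absent from more than ``absence_threshold`` of the
    subjects (contradictory or missing identifications that are invisible
    when brains cannot be compared side by side), and labels used in graphs
    but absent from the shared nomenclature.  The UNKNOWN sentinel is never
    flagged.
    """
    node_counts: dict[str, dict[str, int]] = {}
    for subject_id, graph in cohort.subjects.items():
        for node in graph.nodes.values():
            node_counts.setdefault(node.label, {}).setdefault(subject_id, 0)
            node_counts[node.label][subject_id] += 1
    subject_counts = {label: len(per) for label, per in node_counts.items()}

    n = len(cohort.subjects)
    flagged_missing: dict[str, list[str]] = {}
    not_in_nom: list[str] = []
    nom = cohort.shared_nomenclature
    for label, count in subject_counts.items():
        if label == UNKNOWN_LABEL:
            continue
        if n > 0 and (n - count) / n > absence_threshold:
            flagged_missing[label] = sorted(
                set(cohort.subjects) - set(node_counts[label])
            )
        if nom is not None and not nom.contains(label):
            not_in_nom.append(label)
    return ConsistencyReport(
        n_subjects=n,
        subject_counts=subject_counts,
        node_counts=node_counts,
        flagged_missing=flagged_missing,
        not_in_nomenclature=not_in_nom,
        absence_threshold=absence_threshold,
    )


def paginate(cohort: Cohort, page_size: int, page_index: int) -> list[str]:
    """One page of the lexicographically ordered subject list (0-based)."""
    if page_size < 1:
        raise ValueError("page_size must be >= 1")
    ordered = sorted(cohort.subjects)
    n_pages = max(1, -(-len(ordered) // page_size))
    if not 0 <= page_index < n_pages or (not ordered and page_index > 0):
        raise NotFound(f"page {page_index} out of range (have {n_pages} page(s))")
    return ordered[page_index * page_size : (page_index + 1) * page_size]
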