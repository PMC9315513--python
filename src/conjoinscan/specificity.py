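"""Specificity partition and cohort summaries for screened events.

Each screened event is assigned exactly one label based on which cohort
classes carry junction-spanning evidence and on database annotation:

* ``normal_shared``    -- present in any normal-class cohort, or already
  described as a non-tumoral transcript in a database snapshot;
* ``cancer_shared``    -- absent from normals but present in at least one
  solid-tumor cohort;
* ``leukemia_specific`` -- present only in leukemia-class cohorts (including
  the study's own cohort) and never flagged non-tumoral.

Database membership alone never disqualifies leukemia specificity; only an
explicit non-tumoral association does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean
from typing import Iterable, Mapping, Sequence

from .io import AnnotationRecord, AnnotationSnapshot

LABELS = ("normal_shared", "cancer_shared", "leukemia_specific", "unclassifiable")
COHORT_CLASSES = ("normal", "solid_tumor", "leukemia")


@dataclass
class SpecificityCall:
    event_id: str
    label: str
    present_classes: dict[str, bool] = field(default_factory=dict)
    database_hits: list[AnnotationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown specificity label {self.label!r}")


def annotate_known_models(
    gene5: str, gene3: str, snapshot: AnnotationSnapshot
) -> list[AnnotationRecord]:
    """All snapshot records matching the ordered gene pair; empty list means
    the event is novel with respect to the packaged annotation."""
    return snapshot.lookup(gene5, gene3)


def classify_specificity(
    event_id: str,
    presence: Mapping[str, bool] | Mapping[str, object],
    cohort_classes: Mapping[str, str],
    annotation_hits: Sequence[AnnotationRecord] = (),
) -> SpecificityCall:
    """Label one event from its per-cohort presence and annotation.

    ``presence`` maps cohort id -> presence (bool, or any object with a
    ``present`` attribute such as a PresenceCell).  Every cohort must carry a
    class in ``cohort_classes``.  Events absent from every cohort are
    ``unclassifiable``.
    """
    by_class = {c: False for c in COHORT_CLASSES}
    for cohort_id, cell in presence.items():
        try:
            klass = cohort_classes[cohort_id]
        except KeyError:
            raise ValueError(f"cohort {cohort_id!r} has no assigned class") from None
        if klass not in COHORT_CLASSES:
            raise ValueError(f"unknown cohort class {klass!r} for {cohort_id!r}")
        present = cell.present if hasattr(cell, "present") else bool(cell)
        by_class[klass] = by_class[klass] or present

    hits = list(annotation_hits)
    non_tumoral = any(h.non_tumoral_flag for h in hits)
    if by_class["normal"] or non_tumoral:
        label = "normal_shared"
    elif by_class["solid_tumor"]:
        label = "cancer_shared"
    elif by_class["leukemia"]:
        label = "leukemia_specific"
    else:
        label = "unclassifiable"
    return SpecificityCall(event_id, label, by_class, hits)


def summarize_specificity(
    calls: Iterable[SpecificityCall], denominator: int | None = None
) -> dict:
    """Counts per label, plus one-decimal percentages against ``denominator``
    (e.g. the full conjoined-gene census size) when supplied."""
    counts = {label: 0 for label in LABELS}
    for c in calls:
        counts[c.label] += 1
    out: dict = {"counts": counts, "n": sum(counts.values())}
    if denominator is not None:
        if denominator < counts["leukemia_specific"]:
            raise ValueError("denominator smaller than the leukemia-specific count")
        out["denominator"] = denominator
        out["percentages"] = {
            label: round(100 * n / denominator, 1) for label, n in counts.items()
        }
    return out


@dataclass
class CohortSummary:
    """Per-sample transcriptional-event burden, overall and per risk group."""

    per_sample_counts: dict[str, int]
    groups: dict[str, str]
    overall_mean: float
    overall_range: tuple[int, int]
    group_stats: dict[str, dict]

    @property
    def n_samples(self) -> int:
        return len(self.per_sample_counts)


def summarize_cohort(
    per_sample_counts: Mapping[str, int], groups: Mapping[str, str]
) -> CohortSummary:
    """Mean and range of per-sample event counts, overall and per group.

    An event seen in k samples contributes one incidence to each of the k
    samples.  Every sample must have a group label.
    """
    unknown = sorted(set(per_sample_counts) - set(groups))
    if unknown:
        raise ValueError(f"samples with unknown group: {unknown}")
    if not per_sample_counts:
        raise ValueError("no samples to summarize")
    values = list(per_sample_counts.values())
    group_stats: dict[str, dict] = {}
    for group in sorted(set(groups[s] for s in per_sample_counts)):
        gv = [n for s, n in per_sample_counts.items() if groups[s] == group]
        group_stats[group] = {
            "n_samples": len(gv),
            "mean": mean(gv),
            "range": (min(gv), max(gv)),
        }
    return CohortSummary(
        per_sample_counts=dict(per_sample_counts),
        groups={s: groups[s] for s in per_sample_counts},
        overall_mean=mean(values),
        overall_range=(min(values), max(values)),
        group_stats=group_stats,
    )


def sample_event_counts(
    event_samples: Mapping[str, Iterable[str]], all_samples: Iterable[str] = ()
) -> dict[str, int]:
    """Tally per-sample event counts from event -> positive-sample lists;
    samples listed in ``all_samples`` appear even at count 0."""
    counts: dict[str, int] = {s: 0 for s in all_samples}
    for samples in event_samples.values():
        for s in samples:
            counts[s] = counts.get(s, 0) + 1
    return counts
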