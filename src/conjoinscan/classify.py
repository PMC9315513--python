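"""Classification of candidate fusions by genomic configuration.

Events split into three mutually exclusive categories:

* ``inter_translocation`` -- breakpoints on different chromosomes, compatible
  with an inter-chromosomal rearrangement;
* ``conjoined_gene`` -- same chromosome, the two partner genes overlap or are
  adjacent (read-through / cis-splicing chimera, no structural change needed);
* ``intra_distant`` -- same chromosome but non-adjacent genes, compatible
  with a deletion or inversion.

Orientation compares the partner genes' strands; adjacency, not strand, is
the conjoined-gene criterion (opposite-strand neighbors can still read
through), and no 5'-to-3' coordinate ordering is enforced.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .io import FusionCall, GeneModel

logger = logging.getLogger(__name__)

CATEGORIES = ("conjoined_gene", "intra_distant", "inter_translocation")


@dataclass
class CgRule:
    """Adjacency rule deciding what counts as a conjoined gene.

    max_intervening_genes: how many annotated genes may sit between the two
    partners (0 = strictly contiguous).  max_distance: largest tolerated
    intergenic gap in bp.  Overlapping partners always qualify when
    require_overlap_or_adjacency is set.
    """

    max_intervening_genes: int = 0
    max_distance: int = 2_000_000
    require_overlap_or_adjacency: bool = True

    def __post_init__(self) -> None:
        if self.max_intervening_genes < 0:
            raise ValueError("max_intervening_genes must be >= 0")
        if self.max_distance <= 0:
            raise ValueError("max_distance must be > 0")


@dataclass
class ClassifiedEvent:
    call: FusionCall
    scope: str  # inter | intra
    category: str
    orientation: str  # same | opposite | unknown
    intervening_genes: int | None = None
    genomic_distance: int | None = None

    def __post_init__(self) -> None:
        if self.scope == "inter" and self.category != "inter_translocation":
            raise ValueError("inter-chromosomal events must be inter_translocation")
        if self.category == "conjoined_gene" and self.scope != "intra":
            raise ValueError("conjoined genes must be intra-chromosomal")


def chromosomal_scope(call: FusionCall) -> str:
    """'inter' iff the two breakpoints lie on different chromosomes."""
    return "inter" if call.bp5.chromosome != call.bp3.chromosome else "intra"


def orientation(call: FusionCall, gene_model: GeneModel | None = None) -> str:
    """'same' iff both partner genes are on the same strand.

    Strand comes from the gene model when available, else from breakpoint
    strands carried by the call; unresolvable strands give 'unknown'.
    """

    def resolve(gene: str, bp) -> str | None:
        if gene_model is not None and gene in gene_model:
            return gene_model.strand(gene)
        return bp.strand

    s5 = resolve(call.gene5, call.bp5)
    s3 = resolve(call.gene3, call.bp3)
    if s5 is None or s3 is None:
        logger.warning("%s: strand unresolvable for %s/%s", call.event_id, call.gene5, call.gene3)
        return "unknown"
    return "same" if s5 == s3 else "opposite"


def is_conjoined(
    call: FusionCall, gene_model: GeneModel, rule: CgRule | None = None
) -> tuple[bool, int | None, int | None]:
    """Decide conjoined-gene status for an intra-chromosomal call.

    Returns (is_cg, intervening_gene_count, genomic_distance).  True when the
    partner gene intervals overlap, or when the intervening-gene count and
    the intergenic gap both fall within the rule's bounds.  A partner missing
    from the model yields (False, None, None) with a warning.
    """
    rule = rule or CgRule()
    if chromosomal_scope(call) != "intra":
        raise ValueError(f"{call.event_id}: conjoined-gene test requires intra scope")
    if call.gene5 not in gene_model or call.gene3 not in gene_model:
        logger.warning(
            "%s: gene missing from model (%s, %s); labeling intra_distant",
            call.event_id, call.gene5, call.gene3,
        )
        return False, None, None
    g5, g3 = gene_model.gene(call.gene5), gene_model.gene(call.gene3)
    if g5.chromosome != g3.chromosome:
        return False, None, None
    distance = gene_model.genomic_distance(call.gene5, call.gene3)
    intervening = len(gene_model.genes_between(call.gene5, call.gene3))
    if g5.overlaps(g3):
        return True, intervening, 0
    ok = intervening <= rule.max_intervening_genes and distance <= rule.max_distance
    return ok, intervening, distance


def classify_event(
    call: FusionCall, gene_model: GeneModel | None, rule: CgRule | None = None
) -> ClassifiedEvent:
    scope = chromosomal_scope(call)
    orient = orientation(call, gene_model)
    if scope == "inter":
        return ClassifiedEvent(call, "inter", "inter_translocation", orient)
    if gene_model is None:
        return ClassifiedEvent(call, "intra", "intra_distant", orient)
    cg, intervening, distance = is_conjoined(call, gene_model, rule)
    category = "conjoined_gene" if cg else "intra_distant"
    return ClassifiedEvent(call, "intra", category, orient, intervening, distance)


def classify_all(
    calls: Iterable[FusionCall],
    gene_model: GeneModel | None = None,
    rule: CgRule | None = None,
) -> tuple[list[ClassifiedEvent], Counter]:
    """Classify every call; returns the labeled events and category counts
    (plus orientation tallies under 'orientation_<label>' keys)."""
    events = [classify_event(c, gene_model, rule) for c in calls]
    counts: Counter = Counter()
    for ev in events:
        counts[ev.category] += 1
        counts[f"orientation_{ev.orientation}"] += 1
    return events, counts


def write_classified(events: Sequence[ClassifiedEvent], path: str | Path) -> None:
    """Classified TSV: the fusionmap_like columns plus scope/category/
    orientation/intervening_genes/genomic_distance."""
    import csv

    from .io import FUSIONMAP_LIKE_COLUMNS

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            FUSIONMAP_LIKE_COLUMNS
            + ["scope", "category", "orientation", "intervening_genes", "genomic_distance"]
        )
        for ev in events:
            c = ev.call
            writer.writerow(
                [
                    c.event_id, c.gene5, c.gene3,
                    c.bp5.chromosome, c.bp5.position,
                    c.bp3.chromosome, c.bp3.position,
                    c.junction_seq or "",
                    "" if c.junction_offset is None else c.junction_offset,
                    c.seed_reads, c.sample_id, c.cohort_id,
                    ev.scope, ev.category, ev.orientation,
                    "" if ev.intervening_genes is None else ev.intervening_genes,
                    "" if ev.genomic_distance is None else ev.genomic_distance,
                ]
            )
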