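"""Packaged desk-scale fixtures: the published conjoined-gene census, the
fusion list and the patient cohort table, plus a synthetic mini gene model.

The census fixture (25 cancer-associated conjoined genes) and the fusion
fixture (16 rearrangement events) carry per-cohort presence fractions exactly
as printed; the normal-cohort columns (a CEU RNA-seq population and a normal
tissue RT-PCR panel) are all-zero because every fixture event is
cancer-associated by construction.

The mini gene model returned by :func:`census_gene_model` /
:func:`fusion_gene_model` is synthetic: each gene is a nominal window around
its printed breakpoint (real gene spans are not reproduced), with intervening
filler genes added between the distant intra-chromosomal pairs, mirroring the
fact that in the real genome those pairs are separated by annotated genes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from ..io import (
    AnnotationRecord,
    AnnotationSnapshot,
    Breakpoint,
    FusionCall,
    Gene,
    GeneModel,
)
from ..screen import PresenceCell

#: cohort id -> class, for the fixtures' columns
CENSUS_COHORT_CLASSES: dict[str, str] = {
    "own_cohort": "leukemia",
    "AML": "leukemia",
    "T-ALL_Leucegene": "leukemia",
    "T-ALL_COG": "leukemia",
    "B-ALL": "leukemia",
    "BLCA": "solid_tumor",
    "BRCA": "solid_tumor",
    "CESC": "solid_tumor",
    "COAD": "solid_tumor",
    "KIRC": "solid_tumor",
    "LGG": "solid_tumor",
    "LUAD": "solid_tumor",
    "PRAD": "solid_tumor",
    "SKCM": "solid_tumor",
    "THCA": "solid_tumor",
    "CEU_normal": "normal",
    "normal_panel": "normal",
}

#: size of the full conjoined-gene census the fixtures are a subset of
CG_CENSUS_TOTAL = 229

_ACCESSIONS = {
    ("KLHL22", "SCARF2", "Ensembl"): "ENST00000429594",
    ("KLHL22", "SCARF2", "ConjoinG"): "CGHSA0597",
    ("PPP1R3F", "LL0XNC01-7P3.1", "GenBank"): "LF211393",
}

_META_COLUMNS = {
    "event_id", "gene5", "gene3", "strand5", "strand3",
    "chr5", "pos5", "chr3", "pos3", "annotation", "own_samples",
}

GENE_WINDOW = 1500  # nominal half-width of a fixture gene around its breakpoint


@dataclass
class FixtureEvent:
    """One fixture row: the call plus presence fractions and annotations."""

    call: FusionCall
    strand5: str
    strand3: str
    annotations: list[str]
    samples: list[str]
    presence: dict[str, tuple[int, int]]  # cohort -> (positives, screened)

    def presence_cells(self) -> dict[str, PresenceCell]:
        return {
            cohort: PresenceCell(
                pos,
                screened,
                tuple(self.samples) if cohort == "own_cohort" else (),
            )
            for cohort, (pos, screened) in self.presence.items()
        }


def _read_fixture(name: str) -> list[FixtureEvent]:
    text = resources.files(__package__).joinpath(name).read_text(encoding="utf-8")
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    events = []
    for row in reader:
        ann = [] if row["annotation"] == "-" else row["annotation"].split(";")
        samples = [s for s in row["own_samples"].split(";") if s]
        presence = {}
        for col, value in row.items():
            if col in _META_COLUMNS or value is None:
                continue
            pos, screened = value.split("/")
            presence[col] = (int(pos), int(screened))
        call = FusionCall(
            event_id=row["event_id"],
            gene5=row["gene5"],
            gene3=row["gene3"],
            bp5=Breakpoint(row["chr5"], int(row["pos5"]), row["strand5"]),
            bp3=Breakpoint(row["chr3"], int(row["pos3"]), row["strand3"]),
            sample_id=";".join(samples),
            cohort_id="own_cohort",
        )
        events.append(
            FixtureEvent(call, row["strand5"], row["strand3"], ann, samples, presence)
        )
    return events


def load_cg_census() -> list[FixtureEvent]:
    """The 25 cancer-associated conjoined genes (11 shared with solid tumors,
    14 leukemia-restricted), breakpoint-resolved."""
    return _read_fixture("tables_2_3_cg_fixture.tsv")


def load_fusion_fixture() -> list[FixtureEvent]:
    """The 16 fusion events compatible with chromosomal rearrangements."""
    return _read_fixture("table_4_fusion_fixture.tsv")


def load_cohort_table() -> dict[str, str]:
    """sample id -> MRD risk group (SR / HR) for the 10-patient cohort."""
    text = (
        resources.files(__package__).joinpath("table_1_cohort.tsv").read_text(encoding="utf-8")
    )
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    return {row["sample_id"]: row["mrd_group"] for row in reader}


def census_annotation_snapshot() -> AnnotationSnapshot:
    """Annotation snapshot derived from the fixtures' annotation columns.

    None of the recorded sources carries a non-tumoral association flag, so
    database membership alone never forces an event into the normal-shared
    class.
    """
    records = []
    for ev in load_cg_census() + load_fusion_fixture():
        for source in ev.annotations:
            records.append(
                AnnotationRecord(
                    ev.call.gene5,
                    ev.call.gene3,
                    source,
                    non_tumoral_flag=False,
                    accession=_ACCESSIONS.get((ev.call.gene5, ev.call.gene3, source), ""),
                )
            )
    return AnnotationSnapshot(records)


def _window_gene(name: str, chrom: str, pos: int, strand: str) -> Gene:
    return Gene(name, chrom, max(1, pos - GENE_WINDOW), pos + GENE_WINDOW, strand)


# fillers between the distant intra-chromosomal pairs whose printed gap is
# below the default conjoined-gene distance cutoff (synthetic stand-ins for
# the real intervening annotation)
_FUSION_FILLERS = [
    ("FILLER_ABL1_NUP214_1", "9", 130900000, 130903000, "+"),
    ("FILLER_ABL1_NUP214_2", "9", 131000000, 131003000, "-"),
    ("FILLER_ABL1_NUP214_3", "9", 131100000, 131103000, "+"),
    ("FILLER_MNT_CLUH_1", "17", 2500000, 2503000, "+"),
    ("FILLER_MNT_CLUH_2", "17", 2600000, 2603000, "-"),
    ("FILLER_CTBP1_MAEA_1", "4", 1250000, 1253000, "+"),
    ("FILLER_CTBP1_MAEA_2", "4", 1270000, 1273000, "-"),
]


def _model_from_rows(rows: list[FixtureEvent], fillers=()) -> GeneModel:
    genes: list[Gene] = []
    for ev in rows:
        genes.append(
            _window_gene(ev.call.gene5, ev.call.bp5.chromosome, ev.call.bp5.position, ev.strand5)
        )
        genes.append(
            _window_gene(ev.call.gene3, ev.call.bp3.chromosome, ev.call.bp3.position, ev.strand3)
        )
    genes.extend(Gene(*f) for f in fillers)
    return GeneModel(genes)


def census_gene_model() -> GeneModel:
    """Synthetic mini gene model for the conjoined-gene census fixture."""
    return _model_from_rows(load_cg_census())


def fusion_gene_model() -> GeneModel:
    """Synthetic mini gene model for the fusion fixture, with intervening
    filler genes between the distant same-chromosome pairs."""
    return _model_from_rows(load_fusion_fixture(), _FUSION_FILLERS)
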