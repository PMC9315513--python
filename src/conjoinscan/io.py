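"""Readers, writers and core domain types.

Covers fusion-call tables (a FusionMap-like TSV dialect), gene models (GTF),
genome FASTA, read alignments (SAM) and annotation snapshots standing in for
curated fusion/conjoined-gene databases.

Coordinate conventions: 1-based inclusive everywhere at the interfaces, as in
GTF and the usual ``chr:pos`` breakpoint notation.  Internal half-open
arithmetic never leaks out.
"""

from __future__ import annotations

import csv
from bisect import bisect_left, insort
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pysam
from intervaltree import IntervalTree


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Breakpoint:
    """A genomic breakpoint, 1-based. Strand is optional in raw input."""

    chromosome: str
    position: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"breakpoint position must be >= 1, got {self.position}")
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def locus(self) -> tuple[str, int]:
        return (self.chromosome, self.position)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.chromosome}:{self.position}"


@dataclass
class FusionCall:
    """One raw candidate fusion event as emitted by an upstream caller.

    Identity is the gene pair *plus* both breakpoints: the same gene pair can
    legitimately recur with distinct junctions (breakpoint variants), and such
    variants are distinct events throughout the pipeline.
    """

    event_id: str
    gene5: str
    gene3: str
    bp5: Breakpoint
    bp3: Breakpoint
    junction_seq: str | None = None
    junction_offset: int | None = None  # 0-based index of first 3' arm base
    seed_reads: int = 0
    sample_id: str = ""
    cohort_id: str = ""

    def __post_init__(self) -> None:
        if self.seed_reads < 0:
            raise ValueError("seed_reads must be >= 0")
        if self.junction_seq is not None and self.junction_offset is not None:
            if not (0 < self.junction_offset < len(self.junction_seq)):
                raise ValueError(
                    "junction_offset must lie strictly inside junction_seq"
                )

    @property
    def identity(self) -> tuple:
        return (self.gene5, self.gene3, self.bp5.locus, self.bp3.locus)

    @property
    def gene_pair(self) -> tuple[str, str]:
        return (self.gene5, self.gene3)


@dataclass(frozen=True)
class Gene:
    name: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"gene {self.name}: invalid span {self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name}: unknown strand {self.strand!r}")

    def overlaps(self, other: "Gene") -> bool:
        return self.chromosome == other.chromosome and not (
            self.end < other.start or other.end < self.start
        )


class GeneModel:
    """Interval-indexed gene annotation with neighbor-order queries."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: dict[str, Gene] = {}
        self._trees: dict[str, IntervalTree] = {}
        self._order: dict[str, list[Gene]] = {}
        for g in genes:
            if g.name in self.genes:
                # duplicate annotation rows for one gene: keep the union span
                old = self.genes[g.name]
                if old.chromosome != g.chromosome:
                    raise ValueError(f"gene {g.name} annotated on two chromosomes")
                g = replace(
                    old, start=min(old.start, g.start), end=max(old.end, g.end)
                )
                self._order[g.chromosome].remove(old)
            self.genes[g.name] = g
            tree = self._trees.setdefault(g.chromosome, IntervalTree())
            tree[g.start : g.end + 1] = g.name
            order = self._order.setdefault(g.chromosome, [])
            insort(order, g, key=lambda x: (x.start, x.end, x.name))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, name: str) -> bool:
        return name in self.genes

    def gene(self, name: str) -> Gene:
        return self.genes[name]

    def strand(self, name: str) -> str | None:
        g = self.genes.get(name)
        return g.strand if g else None

    def chromosomes(self) -> list[str]:
        return sorted(self._order)

    def genes_on(self, chromosome: str) -> list[Gene]:
        """Genes on one chromosome in start-coordinate order."""
        return list(self._order.get(chromosome, []))

    def overlapping(self, chromosome: str, start: int, end: int) -> list[Gene]:
        tree = self._trees.get(chromosome)
        if tree is None:
            return []
        hits = [self.genes[iv.data] for iv in tree[start : end + 1]]
        return sorted(hits, key=lambda g: (g.start, g.end, g.name))

    def genes_between(self, a: str, b: str) -> list[Gene]:
        """Genes (other than a, b) overlapping the open gap between a and b.

        Empty when the two gene intervals overlap or touch.
        """
        ga, gb = self.genes[a], self.genes[b]
        if ga.chromosome != gb.chromosome:
            raise ValueError("genes_between requires same-chromosome genes")
        left, right = (ga, gb) if ga.start <= gb.start else (gb, ga)
        if left.end >= right.start:  # overlapping or abutting
            return []
        gap_start, gap_end = left.end + 1, right.start - 1
        if gap_start > gap_end:
            return []
        return [
            g
            for g in self.overlapping(ga.chromosome, gap_start, gap_end)
            if g.name not in (a, b)
        ]

    def genomic_distance(self, a: str, b: str) -> int:
        """Gap in bp between the nearest interval ends; 0 when overlapping."""
        ga, gb = self.genes[a], self.genes[b]
        if ga.chromosome != gb.chromosome:
            raise ValueError("genomic_distance requires same-chromosome genes")
        if ga.overlaps(gb):
            return 0
        left, right = (ga, gb) if ga.start <= gb.start else (gb, ga)
        return right.start - left.end

    def neighbors(self, name: str, k: int = 1) -> list[Gene]:
        """Up to k genes on each side of ``name`` in start order."""
        g = self.genes[name]
        order = self._order[g.chromosome]
        i = order.index(g)
        return order[max(0, i - k) : i] + order[i + 1 : i + 1 + k]

    def nearest_gene(self, chromosome: str, position: int, name: str | None = None) -> Gene | None:
        """Gene nearest to a coordinate; restricted to ``name`` duplicates if given."""
        pool = self._order.get(chromosome, [])
        if name is not None:
            pool = [g for g in pool if g.name == name]
        if not pool:
            return None
        def dist(g: Gene) -> int:
            if g.start <= position <= g.end:
                return 0
            return min(abs(g.start - position), abs(g.end - position))
        return min(pool, key=dist)


@dataclass(frozen=True)
class AnnotationRecord:
    gene5: str
    gene3: str
    source: str
    non_tumoral_flag: bool = False
    accession: str = ""


class AnnotationSnapshot:
    """Local snapshot of known gene-model / fusion-database records.

    Lookup applies the *ordered* gene pair: direction is preserved.
    """

    def __init__(self, records: Iterable[AnnotationRecord]):
        self.records = list(records)
        self._by_pair: dict[tuple[str, str], list[AnnotationRecord]] = {}
        for r in self.records:
            self._by_pair.setdefault((r.gene5, r.gene3), []).append(r)

    def lookup(self, gene5: str, gene3: str) -> list[AnnotationRecord]:
        return list(self._by_pair.get((gene5, gene3), ()))

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ParseError:
    line_number: int
    message: str
    raw: str = ""


@dataclass
class ParseResult:
    """Parsed records plus a report of malformed rows (never silently dropped)."""

    calls: list[FusionCall]
    errors: list[ParseError] = field(default_factory=list)

    def __iter__(self) -> Iterator[FusionCall]:
        return iter(self.calls)

    def __len__(self) -> int:
        return len(self.calls)


# ---------------------------------------------------------------------------
# Fusion-call tables
# ---------------------------------------------------------------------------

FUSIONMAP_LIKE_COLUMNS = [
    "event_id",
    "gene5",
    "gene3",
    "chr5",
    "pos5",
    "chr3",
    "pos3",
    "junction_seq",
    "junction_offset",
    "seed_reads",
    "sample_id",
    "cohort_id",
]

_DIALECTS = {"fusionmap_like", "generic_tsv"}


def read_fusion_table(path: str | Path, dialect: str = "fusionmap_like") -> ParseResult:
    """Read a fusion-call TSV.

    ``fusionmap_like`` requires the full pinned column contract; ``generic_tsv``
    accepts any header containing at least gene5/gene3/chr5/pos5/chr3/pos3.
    Malformed rows are collected with line numbers in the result's error list.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    path = Path(path)
    calls: list[FusionCall] = []
    errors: list[ParseError] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, header required")
        mandatory = (
            FUSIONMAP_LIKE_COLUMNS
            if dialect == "fusionmap_like"
            else ["gene5", "gene3", "chr5", "pos5", "chr3", "pos3"]
        )
        missing = [c for c in mandatory if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing mandatory columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                calls.append(_row_to_call(row, lineno))
            except (ValueError, TypeError, KeyError) as exc:
                errors.append(ParseError(lineno, str(exc), "\t".join(
                    "" if v is None else str(v) for v in row.values())))
    return ParseResult(calls, errors)


def _row_to_call(row: Mapping[str, str], lineno: int) -> FusionCall:
    def get(col: str, default: str = "") -> str:
        v = row.get(col)
        return default if v is None else v.strip()

    jseq = get("junction_seq") or None
    joff_raw = get("junction_offset")
    joff = int(joff_raw) if joff_raw not in ("", "-") else None
    return FusionCall(
        event_id=get("event_id") or f"row{lineno}",
        gene5=get("gene5"),
        gene3=get("gene3"),
        bp5=Breakpoint(get("chr5"), int(get("pos5")), get("strand5") or None),
        bp3=Breakpoint(get("chr3"), int(get("pos3")), get("strand3") or None),
        junction_seq=jseq,
        junction_offset=joff,
        seed_reads=int(get("seed_reads") or 0),
        sample_id=get("sample_id"),
        cohort_id=get("cohort_id"),
    )


def write_fusion_table(calls: Iterable[FusionCall], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(FUSIONMAP_LIKE_COLUMNS)
        for c in calls:
            writer.writerow(
                [
                    c.event_id,
                    c.gene5,
                    c.gene3,
                    c.bp5.chromosome,
                    c.bp5.position,
                    c.bp3.chromosome,
                    c.bp3.position,
                    c.junction_seq or "",
                    "" if c.junction_offset is None else c.junction_offset,
                    c.seed_reads,
                    c.sample_id,
                    c.cohort_id,
                ]
            )


# ---------------------------------------------------------------------------
# Gene models (GTF)
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gene_model(gtf_path: str | Path) -> GeneModel:
    """Build a :class:`GeneModel` from a Gencode-flavor GTF.

    Uses ``gene`` features for spans and ``exon`` features for exon chains.
    When only exon features exist, gene spans are their per-gene union.
    """
    gtf_path = Path(gtf_path)
    spans: dict[str, list] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with gtf_path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{gtf_path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start_s, end_s, _, strand, _, attr = fields[:9]
            start, end = int(start_s), int(end_s)
            if end < start:
                raise ValueError(f"{gtf_path}:{lineno}: end < start")
            if strand not in ("+", "-"):
                raise ValueError(f"{gtf_path}:{lineno}: unknown strand {strand!r}")
            attrs = _parse_gtf_attributes(attr)
            name = attrs.get("gene_name") or attrs.get("gene_id")
            if name is None:
                raise ValueError(f"{gtf_path}:{lineno}: no gene_id/gene_name attribute")
            if feature == "gene":
                spans[name] = [chrom, start, end, strand]
            elif feature == "exon":
                exons.setdefault(name, []).append((start, end))
                if name not in spans:
                    spans[name] = [chrom, start, end, strand]
                else:
                    spans[name][1] = min(spans[name][1], start)
                    spans[name][2] = max(spans[name][2], end)
    genes = [
        Gene(name, chrom, start, end, strand, tuple(sorted(exons.get(name, ()))))
        for name, (chrom, start, end, strand) in spans.items()
    ]
    return GeneModel(genes)


def write_gene_model(model: GeneModel, gtf_path: str | Path) -> None:
    """Emit gene + transcript + exon features in Gencode-flavor GTF."""
    gtf_path = Path(gtf_path)
    with gtf_path.open("w", encoding="utf-8") as fh:
        for chrom in model.chromosomes():
            for g in model.genes_on(chrom):
                base = f'gene_id "{g.name}"; gene_name "{g.name}";'
                fh.write(
                    f"{chrom}\tconjoinscan\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{base}\n"
                )
                if g.exons:
                    tid = f"{g.name}.t1"
                    fh.write(
                        f"{chrom}\tconjoinscan\ttranscript\t{g.start}\t{g.end}\t.\t"
                        f'{g.strand}\t.\t{base} transcript_id "{tid}";\n'
                    )
                    for start, end in g.exons:
                        fh.write(
                            f"{chrom}\tconjoinscan\texon\t{start}\t{end}\t.\t"
                            f'{g.strand}\t.\t{base} transcript_id "{tid}";\n'
                        )


# ---------------------------------------------------------------------------
# Genome FASTA
# ---------------------------------------------------------------------------

def load_genome(fasta_path: str | Path) -> dict[str, str]:
    """Load a (small) genome FASTA fully into memory as uppercase strings."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Alignments (SAM)
# ---------------------------------------------------------------------------

class AlignmentIndex:
    """Per-base depth and read access over a set of ungapped alignments.

    Depth at a base = number of aligned read spans covering it.  Built either
    from a SAM file (via pysam) or directly from in-memory records.
    """

    def __init__(self, reference_lengths: Mapping[str, int]):
        self.reference_lengths = dict(reference_lengths)
        self._depth = {
            name: np.zeros(length + 2, dtype=np.int64)
            for name, length in self.reference_lengths.items()
        }
        self._finalized = False
        self.read_sequences: list[str] = []
        self.n_alignments = 0

    def add(self, chromosome: str, start: int, end: int, sequence: str | None = None) -> None:
        """Add one aligned span, 1-based inclusive coordinates."""
        if chromosome not in self._depth:
            raise ValueError(f"alignment to unknown chromosome {chromosome!r}")
        if self._finalized:
            raise RuntimeError("index already finalized")
        diff = self._depth[chromosome]
        start = max(1, start)
        end = min(self.reference_lengths[chromosome], end)
        if end < start:
            return
        diff[start] += 1
        diff[end + 1] -= 1
        self.n_alignments += 1
        if sequence:
            self.read_sequences.append(sequence)

    def finalize(self) -> "AlignmentIndex":
        if not self._finalized:
            for name in self._depth:
                self._depth[name] = np.cumsum(self._depth[name])
            self._finalized = True
        return self

    def depth(self, chromosome: str, position: int) -> int:
        """Pileup depth at a single 1-based position."""
        self.finalize()
        arr = self._depth.get(chromosome)
        if arr is None:
            raise ValueError(f"unknown chromosome {chromosome!r}")
        if not (1 <= position <= self.reference_lengths[chromosome]):
            return 0
        return int(arr[position])

    def min_depth(self, chromosome: str, start: int, end: int) -> int:
        """Minimum depth over a 1-based inclusive window (clipped to the contig)."""
        self.finalize()
        arr = self._depth.get(chromosome)
        if arr is None:
            raise ValueError(f"unknown chromosome {chromosome!r}")
        length = self.reference_lengths[chromosome]
        start, end = max(1, start), min(length, end)
        if end < start:
            return 0
        return int(arr[start : end + 1].min())


def read_alignments(sam_path: str | Path) -> AlignmentIndex:
    """Load a headered SAM file into an :class:`AlignmentIndex`."""
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=True) as sam:
        lengths = {name: sam.get_reference_length(name) for name in sam.references}
        index = AlignmentIndex(lengths)
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.reference_name is None:
                continue
            index.add(
                aln.reference_name,
                aln.reference_start + 1,
                aln.reference_end if aln.reference_end else aln.reference_start + 1,
                aln.query_sequence,
            )
    return index.finalize()


# ---------------------------------------------------------------------------
# Annotation snapshots & reads
# ---------------------------------------------------------------------------

def read_annotation_snapshot(path: str | Path) -> AnnotationSnapshot:
    """TSV columns: gene5, gene3, source, non_tumoral_flag, accession."""
    records = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            records.append(
                AnnotationRecord(
                    gene5=row["gene5"].strip(),
                    gene3=row["gene3"].strip(),
                    source=row["source"].strip(),
                    non_tumoral_flag=row.get("non_tumoral_flag", "0").strip().lower()
                    in ("1", "true", "yes"),
                    accession=(row.get("accession") or "").strip(),
                )
            )
    return AnnotationSnapshot(records)


def write_annotation_snapshot(snapshot: AnnotationSnapshot, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene5", "gene3", "source", "non_tumoral_flag", "accession"])
        for r in snapshot.records:
            writer.writerow(
                [r.gene5, r.gene3, r.source, int(r.non_tumoral_flag), r.accession]
            )


def read_fastq_sequences(path: str | Path) -> list[str]:
    """Read sequences (only) from an uncompressed FASTQ file."""
    seqs: list[str] = []
    with pysam.FastxFile(str(path)) as fx:
        for entry in fx:
            seqs.append(entry.sequence)
    return seqs


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write (name, sequence) pairs as FASTQ with uniform quality."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
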