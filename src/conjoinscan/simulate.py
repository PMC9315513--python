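"""Self-contained synthetic dataset generator.

Produces a bundle with the evidence structure the filter cascade and the
junction screen assume: a random genome, a gene model with exon chains,
paired-end reads from linear transcripts, chimeric reads across planted
fusion junctions at controlled incidence, a FusionMap-like raw-call table, a
caller blacklist, and a truth manifest for recovery testing.

Planted event classes:

* true events -- ``cg`` (adjacent same-chromosome gene pairs), ``transloc``
  (different chromosomes), ``intra_distant`` (same chromosome, one
  intervening gene);
* artifacts -- one per filter rule: ``blacklisted``, ``shared_breakpoint``,
  ``genomic_match``, ``low_coverage``, ``low_incidence``,
  ``no_junction_support``.  Each artifact violates exactly its designated
  rule at the generator's default margins.

The generator *guarantees* by construction that every true event clears the
default filter thresholds with a 2x margin: breakpoint flanks are topped up
to twice the depth cutoff where Poisson sampling left them short, and the
spanning-read count is raised to the minimum giving twice the incidence
cutoff.  Alignments are emitted from simulation ground truth (no aligner);
chimeric reads appear in the FASTQ only, as an aligner against the linear
genome would not place them.

Determinism: identical SimParams (including seed) reproduce a byte-identical
bundle.  Each stage derives its own child seed so the stages can also be
called individually.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .io import (
    AlignmentIndex,
    Breakpoint,
    FusionCall,
    Gene,
    GeneModel,
    write_fasta,
    write_fastq,
    write_fusion_table,
    write_gene_model,
)
from .filters import Blacklist
from .screen import ScreenConfig, build_junction_reference

TRUE_CLASSES = ("cg", "transloc", "intra_distant")
ARTIFACT_CLASSES = (
    "blacklisted",
    "shared_breakpoint",
    "genomic_match",
    "low_coverage",
    "low_incidence",
    "no_junction_support",
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimParams:
    """Generator configuration.

    ``read_length`` defaults to 76 bp paired-end, the library layout the
    evidence model is calibrated to.  ``depth`` is the mean read coverage per
    transcript base; ``cg_incidence_range`` is the fraction of
    breakpoint-local reads supporting a planted junction.  Event and artifact
    counts are desk-scale defaults sized so that every artifact class is
    represented several times over.
    """

    seed: int = 0
    n_chromosomes: int = 4
    chrom_length: int = 120_000
    n_genes: int = 120
    gene_length_range: tuple[int, int] = (1500, 3000)
    intergenic_range: tuple[int, int] = (300, 800)
    exons_per_gene_range: tuple[int, int] = (2, 4)
    read_length: int = 76
    fragment_mean: float = 200.0
    fragment_sd: float = 30.0
    base_error_rate: float = 0.001
    depth: float = 30.0
    n_cg_events: int = 12
    cg_incidence_range: tuple[float, float] = (0.15, 0.35)
    n_transloc: int = 5
    n_intra_distant: int = 5
    artifact_counts: dict[str, int] = field(
        default_factory=lambda: {k: 5 for k in ARTIFACT_CLASSES}
    )
    min_overhang: int = 8
    min_flank_depth: int = 10
    min_incidence: float = 0.05
    # artifact margins
    low_coverage_depth: float = 4.0
    low_incidence_target: float = 0.03
    low_incidence_depth: float = 60.0
    exact_incidence: bool = False
    chrom_margin: int = 1000
    breakpoint_margin: int = 150

    def __post_init__(self) -> None:
        counts = [
            self.n_chromosomes, self.n_genes, self.n_cg_events,
            self.n_transloc, self.n_intra_distant,
            *self.artifact_counts.values(),
        ]
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if self.chrom_length <= 0 or self.n_chromosomes <= 0:
            raise ValueError("chromosome dimensions must be positive")
        lo, hi = self.cg_incidence_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("cg_incidence_range must lie within (0, 1]")
        if self.read_length < 2 * self.min_overhang:
            raise ValueError("read_length must be >= 2 x min_overhang")
        unknown = set(self.artifact_counts) - set(ARTIFACT_CLASSES)
        if unknown:
            raise ValueError(f"unknown artifact classes: {sorted(unknown)}")

    @property
    def arm_length(self) -> int:
        return self.read_length - self.min_overhang

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


@dataclass
class EventSpec:
    event_id: str
    klass: str
    gene5: str
    gene3: str
    bp5: Breakpoint
    bp3: Breakpoint
    incidence: float
    junction_seq: str
    junction_offset: int
    depth_override: float | None = None  # per-gene depth for both partners
    planted_spanning: int = 0  # filled by simulate_reads
    claimed_seed_reads: int = 0  # what the raw table reports

    @property
    def is_artifact(self) -> bool:
        return self.klass in ARTIFACT_CLASSES


@dataclass
class TruthManifest:
    """Ground-truth ledger for one synthetic bundle."""

    planted_events: list[dict] = field(default_factory=list)
    artifacts: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def all_event_ids(self) -> set[str]:
        return {e["event_id"] for e in self.planted_events} | {
            a["event_id"] for a in self.artifacts
        }

    def true_event_ids(self) -> set[str]:
        return {e["event_id"] for e in self.planted_events}

    def artifact_ids(self, klass: str | None = None) -> set[str]:
        return {
            a["event_id"]
            for a in self.artifacts
            if klass is None or a["artifact_class"] == klass
        }

    def classes_by_id(self) -> dict[str, str]:
        out = {e["event_id"]: e["class"] for e in self.planted_events}
        out.update({a["event_id"]: a["artifact_class"] for a in self.artifacts})
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "planted_events": self.planted_events,
                "artifacts": self.artifacts,
                "warnings": self.warnings,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload


# ---------------------------------------------------------------------------
# Stage 1: genome
# ---------------------------------------------------------------------------

def generate_genome(params: SimParams) -> dict[str, str]:
    """Uniform-random A/C/G/T chromosomes, deterministic per seed."""
    rng = params.rng(0)
    genome: dict[str, str] = {}
    for i in range(params.n_chromosomes):
        arr = _BASES[rng.integers(0, 4, size=params.chrom_length)]
        genome[f"chr{i + 1}"] = arr.tobytes().decode("ascii")
    return genome


# ---------------------------------------------------------------------------
# Stage 2: gene model
# ---------------------------------------------------------------------------

def _make_exons(start: int, end: int, n_exons: int) -> tuple[tuple[int, int], ...]:
    """Exon chain covering [start, end]: n blocks, each exon the leading 70%
    of its block, with first/last exon pinned to the gene ends."""
    span = end - start + 1
    if n_exons <= 1 or span < 4 * n_exons:
        return ((start, end),)
    bounds = [start + round(i * span / n_exons) for i in range(n_exons + 1)]
    exons = []
    for i in range(n_exons):
        b_start, b_end = bounds[i], bounds[i + 1] - 1
        e_end = b_end if i == n_exons - 1 else b_start + max(1, round(0.7 * (b_end - b_start)))
        exons.append((b_start, min(e_end, b_end)))
    return tuple(exons)


def generate_gene_model(params: SimParams, genome: Mapping[str, str]) -> GeneModel:
    """Place ``n_genes`` non-nested genes with intergenic gaps drawn from
    ``intergenic_range``, random strands, and exon chains."""
    rng = params.rng(1)
    genes: list[Gene] = []
    chroms = sorted(genome)
    gi = 0
    for chrom in chroms:
        cursor = params.chrom_margin + 1
        limit = len(genome[chrom]) - params.chrom_margin
        while gi < params.n_genes:
            length = int(rng.integers(params.gene_length_range[0], params.gene_length_range[1] + 1))
            if cursor + length - 1 > limit:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(params.exons_per_gene_range[0], params.exons_per_gene_range[1] + 1))
            start, end = cursor, cursor + length - 1
            genes.append(Gene(f"G{gi:04d}", chrom, start, end, strand, _make_exons(start, end, n_ex)))
            gi += 1
            cursor = end + 1 + int(
                rng.integers(params.intergenic_range[0], params.intergenic_range[1] + 1)
            )
        if gi >= params.n_genes:
            break
    if gi < params.n_genes:
        raise ValueError(
            f"genome too short: placed {gi}/{params.n_genes} genes at minimum spacing"
        )
    return GeneModel(genes)


# ---------------------------------------------------------------------------
# Stage 3: event planting
# ---------------------------------------------------------------------------

def _breakpoint_sites(gene: Gene, margin: int) -> tuple[list[int], list[int]]:
    """(donor, acceptor) candidate coordinates in transcript orientation.

    Donor = transcript-internal exon end; acceptor = transcript-internal exon
    start.  Falls back to an interior point when no exon boundary clears the
    margin from the gene ends.
    """
    lo, hi = gene.start + margin, gene.end - margin
    if gene.strand == "+":
        donors = [e for _, e in gene.exons[:-1] if lo <= e <= hi]
        acceptors = [s for s, _ in gene.exons[1:] if lo <= s <= hi]
    else:
        donors = [s for s, _ in gene.exons[1:] if lo <= s <= hi]
        acceptors = [e for _, e in gene.exons[:-1] if lo <= e <= hi]
    fallback = [gene.start + (gene.end - gene.start) // 2]
    return donors or fallback, acceptors or fallback


class _GenePool:
    """Deterministic allocator over unused genes in placement order."""

    def __init__(self, model: GeneModel):
        self.by_chrom = {c: model.genes_on(c) for c in model.chromosomes()}
        self.used: set[str] = set()

    def take_run(self, n: int, exclude_chrom: str | None = None) -> list[Gene]:
        """n consecutive unused genes on one chromosome."""
        for chrom, genes in self.by_chrom.items():
            if chrom == exclude_chrom:
                continue
            for i in range(len(genes) - n + 1):
                run = genes[i : i + n]
                if all(g.name not in self.used for g in run):
                    self.used.update(g.name for g in run)
                    return run
        raise ValueError(f"gene model exhausted: no free run of {n} genes")

    def take_one(self, exclude_chrom: str | None = None) -> Gene:
        return self.take_run(1, exclude_chrom)[0]


def _junction_for(
    params: SimParams,
    genome: Mapping[str, str],
    gene5: Gene,
    gene3: Gene,
    bp5: int,
    bp3: int,
) -> tuple[str, int]:
    call = FusionCall(
        "tmp", gene5.name, gene3.name,
        Breakpoint(gene5.chromosome, bp5, gene5.strand),
        Breakpoint(gene3.chromosome, bp3, gene3.strand),
    )
    cfg = ScreenConfig(
        read_length=params.read_length,
        min_overhang=params.min_overhang,
        arm_length=params.arm_length,
    )
    jref = build_junction_reference(call, genome, None, cfg)
    return jref.sequence, jref.junction_offset


def plant_events(
    params: SimParams, genome: Mapping[str, str], gene_model: GeneModel
) -> tuple[list[EventSpec], TruthManifest]:
    """Allocate gene pairs and breakpoints for every true event and artifact.

    CG events join the donor site of a gene to the acceptor site of its
    immediate neighbor; intra-distant events skip one intervening gene;
    translocations pair genes on different chromosomes.  Artifact
    construction per class is described in the module docstring.
    """
    rng = params.rng(2)
    pool = _GenePool(gene_model)
    manifest = TruthManifest()
    events: list[EventSpec] = []
    counter = 0

    def incidence() -> float:
        lo, hi = params.cg_incidence_range
        return float(rng.uniform(lo, hi))

    def pick(sites: list[int]) -> int:
        return int(sites[rng.integers(0, len(sites))])

    def make(klass: str, g5: Gene, g3: Gene, inc: float,
             depth_override: float | None = None,
             junction: tuple[str, int] | None = None,
             bp5_pos: int | None = None) -> EventSpec:
        nonlocal counter
        counter += 1
        donor5, _ = _breakpoint_sites(g5, params.breakpoint_margin)
        _, acceptor3 = _breakpoint_sites(g3, params.breakpoint_margin)
        p5 = bp5_pos if bp5_pos is not None else pick(donor5)
        p3 = pick(acceptor3)
        if junction is None:
            jseq, joff = _junction_for(params, genome, g5, g3, p5, p3)
        else:
            jseq, joff = junction
        return EventSpec(
            event_id=f"EV{counter:04d}",
            klass=klass,
            gene5=g5.name,
            gene3=g3.name,
            bp5=Breakpoint(g5.chromosome, p5, g5.strand),
            bp3=Breakpoint(g3.chromosome, p3, g3.strand),
            incidence=inc,
            junction_seq=jseq,
            junction_offset=joff,
            depth_override=depth_override,
        )

    # true events
    for _ in range(params.n_cg_events):
        g5, g3 = pool.take_run(2)
        events.append(make("cg", g5, g3, incidence()))
    for _ in range(params.n_transloc):
        g5 = pool.take_one()
        g3 = pool.take_one(exclude_chrom=g5.chromosome)
        events.append(make("transloc", g5, g3, incidence()))
    for _ in range(params.n_intra_distant):
        g5, _mid, g3 = pool.take_run(3)
        events.append(make("intra_distant", g5, g3, incidence()))

    # artifacts
    counts = params.artifact_counts
    for _ in range(counts.get("blacklisted", 0)):
        g5, g3 = pool.take_run(2)
        ev = make("blacklisted", g5, g3, incidence())
        events.append(ev)

    n_shared = counts.get("shared_breakpoint", 0)
    if n_shared:
        if n_shared < 2:
            raise ValueError("shared_breakpoint artifacts require a count >= 2")
        donor = pool.take_one()
        donor_sites, _ = _breakpoint_sites(donor, params.breakpoint_margin)
        shared_pos = int(donor_sites[0])
        for _ in range(n_shared):
            g3 = pool.take_one(exclude_chrom=donor.chromosome)
            events.append(
                make("shared_breakpoint", donor, g3, incidence(), bp5_pos=shared_pos)
            )

    for _ in range(counts.get("genomic_match", 0)):
        g5, g3 = pool.take_run(2)
        donor5, _ = _breakpoint_sites(g5, params.breakpoint_margin)
        p5 = int(donor5[0])
        seq = genome[g5.chromosome]
        arm = params.arm_length
        jseq = seq[p5 - arm : p5 + arm]  # contiguous genome window through bp5
        ev = make("genomic_match", g5, g3, incidence(), junction=(jseq, arm), bp5_pos=p5)
        events.append(ev)

    for _ in range(counts.get("low_coverage", 0)):
        g5, g3 = pool.take_run(2)
        events.append(
            make("low_coverage", g5, g3, incidence(), depth_override=params.low_coverage_depth)
        )

    for _ in range(counts.get("low_incidence", 0)):
        g5, g3 = pool.take_run(2)
        events.append(
            make(
                "low_incidence", g5, g3, params.low_incidence_target,
                depth_override=params.low_incidence_depth,
            )
        )

    for _ in range(counts.get("no_junction_support", 0)):
        g5, g3 = pool.take_run(2)
        events.append(make("no_junction_support", g5, g3, 0.0))

    # manifest (spanning counts are completed by simulate_reads)
    for ev in events:
        entry = {
            "event_id": ev.event_id,
            "gene5": ev.gene5,
            "gene3": ev.gene3,
            "bp5": f"{ev.bp5.chromosome}:{ev.bp5.position}",
            "bp3": f"{ev.bp3.chromosome}:{ev.bp3.position}",
            "incidence": ev.incidence,
            "expected_spanning_reads": None,
        }
        if ev.is_artifact:
            entry["artifact_class"] = ev.klass
            manifest.artifacts.append(entry)
        else:
            entry["class"] = ev.klass
            manifest.planted_events.append(entry)
    return events, manifest


# ---------------------------------------------------------------------------
# Stage 4: reads
# ---------------------------------------------------------------------------

def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    chars = list(seq)
    positions = rng.choice(len(seq), size=k, replace=False)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


@dataclass
class SimReads:
    """Simulated read set: pairs plus ground-truth alignments."""

    pairs: list[tuple[str, str, str]]  # (name, seq1, seq2)
    sam_records: list[tuple[str, int, str, int, str]]  # (qname, flag, chrom, pos1, seq)
    alignments: AlignmentIndex

    def sequences(self) -> list[str]:
        out = []
        for _, s1, s2 in self.pairs:
            out.append(s1)
            out.append(s2)
        return out


def simulate_reads(
    params: SimParams,
    genome: Mapping[str, str],
    gene_model: GeneModel,
    events: list[EventSpec],
    manifest: TruthManifest | None = None,
) -> SimReads:
    """Paired-end reads from linear gene loci plus chimeric junction reads.

    Linear fragments are uniform over each gene span (one transcript per
    gene, splicing not simulated in the reads).  Chimeric reads per event are
    drawn so the spanning fraction at the breakpoint matches the event's
    incidence (binomially in the default mode, by rounding in
    ``exact_incidence`` mode), then clamped upward to the generator's
    evidence-floor guarantee for retained classes.  Chimeric pairs appear in
    the FASTQ only; SAM records cover the linear reads.
    """
    rng = params.rng(3)
    L = params.read_length
    depth_by_gene: dict[str, float] = {}
    for ev in events:
        if ev.depth_override is not None:
            depth_by_gene[ev.gene5] = ev.depth_override
            depth_by_gene[ev.gene3] = ev.depth_override

    lengths = {c: len(s) for c, s in genome.items()}
    index = AlignmentIndex(lengths)
    pairs: list[tuple[str, str, str]] = []
    sam_records: list[tuple[str, int, str, int, str]] = []

    def add_linear(name: str, chrom: str, start1: int, fwd: bool) -> None:
        seq = genome[chrom][start1 - 1 : start1 - 1 + L]
        index.add(chrom, start1, start1 + L - 1, seq)
        sam_records.append((name, 0 if fwd else 16, chrom, start1, seq))

    # linear fragments per gene
    for chrom in gene_model.chromosomes():
        for gene in gene_model.genes_on(chrom):
            depth = depth_by_gene.get(gene.name, params.depth)
            span = gene.end - gene.start + 1
            n_frag = max(1, round(depth * span / (2 * L)))
            frags = np.clip(
                np.rint(rng.normal(params.fragment_mean, params.fragment_sd, n_frag)),
                L + 10, span,
            ).astype(int)
            starts = gene.start + (rng.random(n_frag) * (span - frags + 1)).astype(int)
            for i in range(n_frag):
                f0, flen = int(starts[i]), int(frags[i])
                name = f"{gene.name}_f{i}"
                add_linear(name + "/1", chrom, f0, True)
                r2_start = f0 + flen - L
                add_linear(name + "/2", chrom, r2_start, False)
                s1 = _mutate(genome[chrom][f0 - 1 : f0 - 1 + L], rng, params.base_error_rate)
                s2_f = genome[chrom][r2_start - 1 : r2_start - 1 + L]
                s2 = _mutate(_revcomp(s2_f), rng, params.base_error_rate)
                pairs.append((name, s1, s2))

    # top-up: guarantee 2x the flank-depth threshold around retained events
    flank = 50
    target = 2 * params.min_flank_depth
    fill_i = 0
    for ev in events:
        if ev.klass == "low_coverage":
            continue
        for bp in (ev.bp5, ev.bp3):
            lo, hi = bp.position - flank, bp.position + flank
            deficit = target - _window_min(index, bp.chromosome, lo, hi)
            while deficit > 0:
                for off in (-flank, -flank // 2, 0):
                    start1 = max(1, bp.position + off)
                    name = f"fill_{fill_i}"
                    fill_i += 1
                    add_linear(name + "/1", bp.chromosome, start1, True)
                    seq = genome[bp.chromosome][start1 - 1 : start1 - 1 + L]
                    pairs.append((name, seq, _revcomp(seq)))
                    # mate: reuse the same window reverse-complemented; the
                    # second read is aligned on the reverse strand in place
                    index.add(bp.chromosome, start1, start1 + L - 1, _revcomp(seq))
                    sam_records.append((name + "/2", 16, bp.chromosome, start1, seq))
                deficit = target - _window_min(index, bp.chromosome, lo, hi)

    index.finalize()

    # chimeric reads
    for ev in events:
        d5 = index.depth(*ev.bp5.locus)
        d3 = index.depth(*ev.bp3.locus)
        nbar = (d5 + d3) / 2
        if ev.klass == "no_junction_support":
            ev.planted_spanning = 0
            ev.claimed_seed_reads = max(2, round(0.2 * nbar / 0.8))
            _record_spanning(manifest, ev)
            continue
        inc = ev.incidence
        if inc * nbar < 1 and manifest is not None:
            manifest.warnings.append(
                f"{ev.event_id}: expected spanning reads below 1 "
                f"(incidence {inc:.3f} x depth {nbar:.1f})"
            )
        if params.exact_incidence:
            s = max(1, round(inc * nbar / (1 - inc))) if inc < 1 else max(1, round(nbar))
        else:
            trials = max(1, round(nbar / (1 - inc))) if inc < 1 else max(1, round(nbar))
            s = int(rng.binomial(trials, inc))
        if ev.klass == "low_incidence":
            # clamp downward until the measured incidence sits safely below
            # the cutoff (the artifact must fail exactly this rule)
            s = max(1, s)
            while s > 1 and (s / (s + d5) + s / (s + d3)) / 2 >= 0.9 * params.min_incidence:
                s -= 1
            if (s / (s + d5) + s / (s + d3)) / 2 >= params.min_incidence and manifest is not None:
                manifest.warnings.append(
                    f"{ev.event_id}: low_incidence artifact not below the cutoff "
                    f"at depth {nbar:.1f}; raise low_incidence_depth"
                )
        else:
            # evidence floor: mean per-locus incidence >= 2x the cutoff
            floor = 2 * params.min_incidence
            while s < 1 or (s / (s + d5) + s / (s + d3)) / 2 < floor:
                s += 1
        ev.planted_spanning = s
        ev.claimed_seed_reads = s
        _record_spanning(manifest, ev)

        jseq, joff = ev.junction_seq, ev.junction_offset
        lo = max(0, joff - (L - params.min_overhang))
        hi = min(joff - params.min_overhang, len(jseq) - L)
        g5 = gene_model.gene(ev.gene5)
        for i in range(s):
            start = int(rng.integers(lo, hi + 1))
            r1 = _mutate(jseq[start : start + L], rng, params.base_error_rate)
            mlo, mhi = g5.start, max(g5.start, g5.end - L + 1)
            m0 = int(rng.integers(mlo, mhi + 1))
            mate = _revcomp(genome[g5.chromosome][m0 - 1 : m0 - 1 + L])
            pairs.append((f"{ev.event_id}_chim{i}", r1, _mutate(mate, rng, params.base_error_rate)))

    return SimReads(pairs, sam_records, index)


def _record_spanning(manifest: TruthManifest | None, ev: EventSpec) -> None:
    if manifest is None:
        return
    for bucket in (manifest.planted_events, manifest.artifacts):
        for entry in bucket:
            if entry["event_id"] == ev.event_id:
                entry["expected_spanning_reads"] = ev.planted_spanning


def _window_min(index: AlignmentIndex, chrom: str, lo: int, hi: int) -> int:
    # min depth over a window on a *non-finalized* index: compute from the
    # diff array without destroying it
    diff = index._depth[chrom]
    length = index.reference_lengths[chrom]
    lo, hi = max(1, lo), min(length, hi)
    prefix = np.cumsum(diff[: hi + 1])
    return int(prefix[lo : hi + 1].min())


def _revcomp(seq: str) -> str:
    from ._util import revcomp

    return revcomp(seq)


# ---------------------------------------------------------------------------
# Stage 5: raw-call table
# ---------------------------------------------------------------------------

def emit_raw_calls(
    events: list[EventSpec], manifest: TruthManifest, n_samples: int = 10
) -> list[FusionCall]:
    """One FusionMap-like row per planted event and artifact.

    Sample ids are assigned round-robin over a simulated cohort, so that
    per-sample filter statistics have several samples to aggregate over.
    """
    calls = []
    ids = manifest.all_event_ids()
    for i, ev in enumerate(events):
        if ev.event_id not in ids:
            raise ValueError(f"{ev.event_id} missing from manifest")
        calls.append(
            FusionCall(
                event_id=ev.event_id,
                gene5=ev.gene5,
                gene3=ev.gene3,
                bp5=ev.bp5,
                bp3=ev.bp3,
                junction_seq=ev.junction_seq,
                junction_offset=ev.junction_offset,
                seed_reads=ev.claimed_seed_reads,
                sample_id=f"S{i % n_samples + 1:02d}",
                cohort_id="own_cohort",
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Bundle orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimBundle:
    params: SimParams
    genome: dict[str, str]
    gene_model: GeneModel
    events: list[EventSpec]
    manifest: TruthManifest
    reads: SimReads
    calls: list[FusionCall]
    blacklist: Blacklist


def generate_bundle(params: SimParams) -> SimBundle:
    """Run all generator stages and assemble the bundle."""
    genome = generate_genome(params)
    gene_model = generate_gene_model(params, genome)
    events, manifest = plant_events(params, genome, gene_model)
    reads = simulate_reads(params, genome, gene_model, events, manifest)
    calls = emit_raw_calls(events, manifest)
    blacklist = Blacklist.from_pairs(
        (ev.gene5, ev.gene3) for ev in events if ev.klass == "blacklisted"
    )
    return SimBundle(params, genome, gene_model, events, manifest, reads, calls, blacklist)


def write_bundle(bundle: SimBundle, outdir: str | Path) -> dict[str, Path]:
    """Serialize a bundle: FASTA, GTF, paired FASTQ, SAM, raw-call TSV,
    blacklist TSV and manifest JSON. Returns the written paths."""
    import pysam

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "gtf": outdir / "genes.gtf",
        "fastq1": outdir / "reads_1.fastq",
        "fastq2": outdir / "reads_2.fastq",
        "sam": outdir / "alignments.sam",
        "calls": outdir / "raw_calls.tsv",
        "blacklist": outdir / "blacklist.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_fasta(bundle.genome, paths["genome"])
    write_gene_model(bundle.gene_model, paths["gtf"])
    write_fastq([(n + "/1", s1) for n, s1, _ in bundle.reads.pairs], paths["fastq1"])
    write_fastq([(n + "/2", s2) for n, _, s2 in bundle.reads.pairs], paths["fastq2"])

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [
                {"SN": name, "LN": len(seq)}
                for name, seq in bundle.genome.items()
            ],
        }
    )
    with pysam.AlignmentFile(str(paths["sam"]), "w", header=header) as out:
        for qname, flag, chrom, pos1, seq in bundle.reads.sam_records:
            a = pysam.AlignedSegment(header)
            a.query_name = qname
            a.flag = flag
            a.reference_name = chrom
            a.reference_start = pos1 - 1
            a.mapping_quality = 60
            a.cigarstring = f"{len(seq)}M"
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            out.write(a)

    write_fusion_table(bundle.calls, paths["calls"])
    with paths["blacklist"].open("w", encoding="utf-8") as fh:
        for pair in sorted(tuple(sorted(p)) for p in bundle.blacklist.pairs):
            fh.write("\t".join(pair) + "\n")
    bundle.manifest.to_json(paths["manifest"])
    return paths


# ---------------------------------------------------------------------------
# Cohort emulation for the junction screen
# ---------------------------------------------------------------------------

def simulate_cohort_reads(
    params: SimParams,
    genome: Mapping[str, str],
    gene_model: GeneModel,
    events: list[EventSpec],
    inclusion: Mapping[str, Mapping[str, Iterable[str]]],
    seed: int | None = None,
    spanning_per_event: int = 4,
    background_reads_per_gene: int = 10,
) -> dict[str, dict[str, list[str]]]:
    """Per-cohort, per-sample read sets for junction screening.

    ``inclusion``: {cohort_id: {sample_id: [event ids carried]}}.  Samples
    carrying an event receive spanning reads across its junction; every
    sample receives linear background reads from the event parent loci, so
    that one-side matches exist everywhere.
    """
    rng = np.random.default_rng([seed if seed is not None else params.seed, 4])
    L = params.read_length
    by_id = {ev.event_id: ev for ev in events}
    out: dict[str, dict[str, list[str]]] = {}
    for cohort_id, samples in inclusion.items():
        out[cohort_id] = {}
        for sample_id, carried in samples.items():
            reads: list[str] = []
            for ev in events:
                g5 = gene_model.gene(ev.gene5)
                for _ in range(background_reads_per_gene):
                    m0 = int(rng.integers(g5.start, max(g5.start, g5.end - L + 1) + 1))
                    reads.append(genome[g5.chromosome][m0 - 1 : m0 - 1 + L])
            for eid in carried:
                ev = by_id[eid]
                jseq, joff = ev.junction_seq, ev.junction_offset
                lo = max(0, joff - (L - params.min_overhang))
                hi = min(joff - params.min_overhang, len(jseq) - L)
                n = max(1, int(rng.poisson(spanning_per_event)))
                for _ in range(n):
                    start = int(rng.integers(lo, hi + 1))
                    reads.append(_mutate(jseq[start : start + L], rng, params.base_error_rate))
            out[cohort_id][sample_id] = reads
    return out
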