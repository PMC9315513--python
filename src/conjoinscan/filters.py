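"""Six-rule filter cascade reducing raw fusion calls to candidate fusions.

Rules, in application order:

1. blacklist              -- caller-curated artifact gene pairs / regions
2. shared_breakpoint      -- promiscuous breakpoints recurring across events
                             with distinct gene pairs
3. genomic_match          -- junction collinear with the reference genome
4. flank_coverage         -- read depth < threshold around either breakpoint
5. incidence              -- junction-supporting reads below a minimum fraction
                             of all reads at the breakpoints
6. junction_support       -- no reads spanning the junction after remapping

Boundary semantics are strict-below: depth exactly at the threshold and
incidence exactly at the minimum both survive.  The report carries both the
sequential removals (order-dependent) and per-rule incidences evaluated
independently on the raw list (order-free; fractions may sum above 1 because
one event can violate several rules).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._util import hamming_leq, revcomp
from .io import AlignmentIndex, FusionCall, GeneModel
from .screen import JunctionIndex, JunctionRef, ScreenConfig, build_junction_reference

RULES = (
    "blacklist",
    "shared_breakpoint",
    "genomic_match",
    "flank_coverage",
    "incidence",
    "junction_support",
)


@dataclass
class Blacklist:
    """Caller blacklist: unordered gene pairs plus genomic regions."""

    pairs: set[frozenset[str]] = field(default_factory=set)
    regions: list[tuple[str, int, int]] = field(default_factory=list)  # 1-based incl.

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Blacklist":
        return cls(pairs={frozenset(p) for p in pairs})

    def matches_pair(self, gene5: str, gene3: str) -> bool:
        return frozenset((gene5, gene3)) in self.pairs

    def matches_breakpoint(self, chromosome: str, position: int) -> bool:
        return any(
            chromosome == c and s <= position <= e for c, s, e in self.regions
        )

    def matches(self, call: FusionCall) -> bool:
        return (
            self.matches_pair(call.gene5, call.gene3)
            or self.matches_breakpoint(*call.bp5.locus)
            or self.matches_breakpoint(*call.bp3.locus)
        )


def read_blacklist(path: str | Path) -> Blacklist:
    """Two-column rows are gene pairs; three-column rows are BED regions
    (0-based half-open, converted to 1-based inclusive)."""
    bl = Blacklist()
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not line.strip() or line.startswith("#"):
                continue
            if len(fields) == 2:
                bl.pairs.add(frozenset(fields))
            elif len(fields) >= 3:
                bl.regions.append((fields[0], int(fields[1]) + 1, int(fields[2])))
            else:
                raise ValueError(f"blacklist line not parseable: {line!r}")
    return bl


@dataclass
class FilterConfig:
    blacklist: Blacklist = field(default_factory=Blacklist)
    min_flank_depth: int = 10
    flank_window: int = 50
    min_incidence: float = 0.05
    max_junction_mismatches: int = 2
    min_overhang: int = 8
    min_spanning_reads_after_remap: int = 1
    shared_breakpoint_min_partners: int = 2

    def __post_init__(self) -> None:
        if self.min_flank_depth < 1:
            raise ValueError("min_flank_depth must be >= 1")
        if not (0 < self.min_incidence <= 1):
            raise ValueError("min_incidence must lie in (0, 1]")
        if self.min_overhang < 1:
            raise ValueError("min_overhang must be >= 1")

    def screen_config(self) -> ScreenConfig:
        return ScreenConfig(
            min_overhang=self.min_overhang,
            max_mismatches=self.max_junction_mismatches,
        )


# ---------------------------------------------------------------------------
# Individual rules: each returns (kept, removed)
# ---------------------------------------------------------------------------

def filter_blacklist(
    events: Sequence[FusionCall], config: FilterConfig
) -> tuple[list[FusionCall], list[FusionCall]]:
    kept, removed = [], []
    for e in events:
        (removed if config.blacklist.matches(e) else kept).append(e)
    return kept, removed


def filter_shared_breakpoints(
    events: Sequence[FusionCall], config: FilterConfig
) -> tuple[list[FusionCall], list[FusionCall]]:
    """Remove events whose exact breakpoint coordinate recurs across events
    with distinct gene pairs (promiscuous-breakpoint artifacts).

    Breakpoint variants of a single gene pair are *not* penalized: sharing
    only counts across different gene pairs.
    """
    partners: dict[tuple[str, int], set[tuple[str, str]]] = {}
    for e in events:
        for bp in (e.bp5, e.bp3):
            partners.setdefault(bp.locus, set()).add(e.gene_pair)
    kept, removed = [], []
    for e in events:
        shared = any(
            len(partners[bp.locus]) >= config.shared_breakpoint_min_partners
            for bp in (e.bp5, e.bp3)
        )
        (removed if shared else kept).append(e)
    return kept, removed


def _find_hamming_match(
    query: str, genome: Mapping[str, str], max_mismatches: int
) -> bool:
    """Pigeonhole-seeded scan: does ``query`` (either strand) occur contiguously
    in the genome with at most ``max_mismatches`` substitutions?

    With <= m mismatches, at least one of m+1 equal chunks matches exactly;
    exact chunk hits anchor full-length Hamming verification.
    """
    n_chunks = max_mismatches + 1
    for oriented in (query, revcomp(query)):
        L = len(oriented)
        bounds = [round(i * L / n_chunks) for i in range(n_chunks + 1)]
        for ci in range(n_chunks):
            lo, hi = bounds[ci], bounds[ci + 1]
            chunk = oriented[lo:hi]
            if not chunk:
                continue
            for seq in genome.values():
                pos = seq.find(chunk)
                while pos != -1:
                    start = pos - lo
                    if 0 <= start <= len(seq) - L and hamming_leq(
                        oriented, seq[start : start + L], max_mismatches
                    ):
                        return True
                    pos = seq.find(chunk, pos + 1)
    return False


def filter_genomic_match(
    events: Sequence[FusionCall],
    genome: Mapping[str, str],
    config: FilterConfig,
) -> tuple[list[FusionCall], list[FusionCall]]:
    """Remove events whose full junction sequence aligns contiguously (no
    gaps, either strand) to the genome within the mismatch budget."""
    kept, removed = [], []
    for e in events:
        if e.junction_seq is None:
            raise ValueError(f"{e.event_id}: junction_seq required for genomic-match test")
        hit = _find_hamming_match(e.junction_seq, genome, config.max_junction_mismatches)
        (removed if hit else kept).append(e)
    return kept, removed


def _flank_windows(bp, window: int) -> list[tuple[int, int]]:
    return [(bp.position - window + 1, bp.position), (bp.position, bp.position + window - 1)]


def filter_flank_coverage(
    events: Sequence[FusionCall],
    alignments: AlignmentIndex,
    config: FilterConfig,
) -> tuple[list[FusionCall], list[FusionCall]]:
    """Remove events where any of the four breakpoint-flanking windows drops
    below ``min_flank_depth`` (strictly below; equality survives)."""
    kept, removed = [], []
    for e in events:
        low = False
        for bp in (e.bp5, e.bp3):
            if bp.chromosome not in alignments.reference_lengths:
                raise ValueError(
                    f"{e.event_id}: breakpoint chromosome {bp.chromosome!r} absent from alignments"
                )
            for start, end in _flank_windows(bp, config.flank_window):
                if alignments.min_depth(bp.chromosome, start, end) < config.min_flank_depth:
                    low = True
        (removed if low else kept).append(e)
    return kept, removed


def event_incidence(call: FusionCall, alignments: AlignmentIndex) -> float | None:
    """Fraction of breakpoint-local reads supporting the junction.

    Per parent locus: seed_reads / (seed_reads + linear depth at the
    breakpoint base); the two loci are averaged.  None when there is no read
    evidence at all (no seed reads, no linear coverage).
    """
    s = call.seed_reads
    depths = [alignments.depth(*call.bp5.locus), alignments.depth(*call.bp3.locus)]
    if s == 0 and sum(depths) == 0:
        return None
    fractions = [s / (s + d) if (s + d) > 0 else 0.0 for d in depths]
    return sum(fractions) / 2


def filter_incidence(
    events: Sequence[FusionCall],
    alignments: AlignmentIndex,
    config: FilterConfig,
) -> tuple[list[FusionCall], list[FusionCall]]:
    """Remove events whose junction incidence is strictly below
    ``min_incidence``; events with zero evidence are removed outright."""
    kept, removed = [], []
    for e in events:
        inc = event_incidence(e, alignments)
        if inc is None or inc < config.min_incidence:
            removed.append(e)
        else:
            kept.append(e)
    return kept, removed


def filter_junction_support(
    events: Sequence[FusionCall],
    reads: Iterable[str],
    config: FilterConfig,
    genome: Mapping[str, str] | None = None,
    gene_model: GeneModel | None = None,
) -> tuple[list[FusionCall], list[FusionCall]]:
    """Remap reads on each event's junction sequence; remove events with
    fewer than ``min_spanning_reads_after_remap`` reads spanning the joint
    with the minimum overhang on both sides."""
    screen_cfg = config.screen_config()
    junctions: list[JunctionRef] = []
    for e in events:
        jref = build_junction_reference(e, genome, gene_model, screen_cfg)
        if len(jref.sequence) < 2 * config.min_overhang:
            raise ValueError(f"{e.event_id}: junction shorter than 2 x min_overhang")
        junctions.append(jref)
    counts = JunctionIndex(junctions, screen_cfg).count(reads)
    kept, removed = [], []
    for e, n in zip(events, counts):
        (kept if n >= config.min_spanning_reads_after_remap else removed).append(e)
    return kept, removed


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    n_raw: int
    n_survivors: int
    independent_counts: dict[str, int]
    independent_fractions: dict[str, float]
    per_sample_fractions: dict[str, dict[str, float]]
    sequential_removals: list[tuple[str, int]]
    audit: dict[str, list[str]]  # removed event -> violated rules

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "n_raw": self.n_raw,
                "n_survivors": self.n_survivors,
                "independent_counts": self.independent_counts,
                "independent_fractions": self.independent_fractions,
                "per_sample_fractions": self.per_sample_fractions,
                "sequential_removals": self.sequential_removals,
                "audit": self.audit,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload


def run_cascade(
    events: Sequence[FusionCall],
    genome: Mapping[str, str],
    alignments: AlignmentIndex,
    config: FilterConfig,
    reads: Sequence[str] | None = None,
    gene_model: GeneModel | None = None,
) -> tuple[list[FusionCall], FilterReport]:
    """Apply the six rules in order and assemble the report.

    ``reads`` are the original (FASTQ) read sequences used for junction
    remapping; when omitted, the aligned read sequences from ``alignments``
    are used instead.  Per-rule incidences are additionally evaluated
    independently on the raw list, pooled and per sample.
    """
    if reads is None:
        reads = alignments.read_sequences
    events = list(events)

    def stage(name: str, evs: Sequence[FusionCall]):
        if name == "blacklist":
            return filter_blacklist(evs, config)
        if name == "shared_breakpoint":
            return filter_shared_breakpoints(evs, config)
        if name == "genomic_match":
            return filter_genomic_match(evs, genome, config)
        if name == "flank_coverage":
            return filter_flank_coverage(evs, alignments, config)
        if name == "incidence":
            return filter_incidence(evs, alignments, config)
        if name == "junction_support":
            return filter_junction_support(evs, reads, config, genome, gene_model)
        raise AssertionError(name)

    # independent evaluation on the raw list
    independent: dict[str, set[str]] = {}
    for name in RULES:
        _, removed = stage(name, events)
        independent[name] = {e.event_id for e in removed}

    # sequential application
    current = events
    sequential: list[tuple[str, int]] = []
    removed_at: dict[str, str] = {}
    for name in RULES:
        kept, removed = stage(name, current)
        sequential.append((name, len(removed)))
        for e in removed:
            removed_at[e.event_id] = name
        current = kept

    n_raw = len(events)
    audit: dict[str, list[str]] = {}
    for e in events:
        if e.event_id not in removed_at:
            continue
        rules = [name for name in RULES if e.event_id in independent[name]]
        if removed_at[e.event_id] not in rules:
            rules.append(removed_at[e.event_id])
        audit[e.event_id] = rules

    samples = sorted({e.sample_id for e in events})
    per_sample: dict[str, dict[str, float]] = {}
    for sid in samples:
        ids = {e.event_id for e in events if e.sample_id == sid}
        per_sample[sid] = {
            name: (len(independent[name] & ids) / len(ids)) if ids else 0.0
            for name in RULES
        }

    report = FilterReport(
        n_raw=n_raw,
        n_survivors=len(current),
        independent_counts={k: len(v) for k, v in independent.items()},
        independent_fractions={
            k: (len(v) / n_raw if n_raw else 0.0) for k, v in independent.items()
        },
        per_sample_fractions=per_sample,
        sequential_removals=sequential,
        audit=audit,
    )
    return current, report
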