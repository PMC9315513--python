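"""Junction-spanning read screen across cohorts.

For every candidate event a junction reference (5' arm + 3' arm around the
fusion joint) is built, reads are aligned to it ungapped with a small mismatch
budget, and a read counts as *spanning* only when it covers a minimum overhang
on both sides of the joint — reads confined to one arm are explicitly excluded
as false-positive matches.  Per-cohort tallies are assembled into an
event x cohort presence matrix of ``positives/screened`` cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._util import hamming_leq, revcomp
from .io import FusionCall, GeneModel


@dataclass
class ScreenConfig:
    """Knobs of the junction screen.

    arm_length defaults to read_length - min_overhang so that any read placed
    with the minimum overhang still fits entirely on the junction.
    """

    read_length: int = 76
    min_overhang: int = 8
    max_mismatches: int = 2
    presence_min_reads: int = 1
    arm_length: int | None = None
    kmer_size: int = 13

    def __post_init__(self) -> None:
        if self.arm_length is None:
            self.arm_length = self.read_length - self.min_overhang
        if self.min_overhang < 1:
            raise ValueError("min_overhang must be >= 1")
        if self.arm_length < self.min_overhang:
            raise ValueError("arm_length must be >= min_overhang")
        if self.presence_min_reads < 1:
            raise ValueError("presence_min_reads must be >= 1")


@dataclass(frozen=True)
class JunctionRef:
    """Junction mini-reference: sequence plus the 0-based offset of the first
    3'-arm base."""

    event_id: str
    sequence: str
    junction_offset: int

    def __post_init__(self) -> None:
        if not (0 < self.junction_offset < len(self.sequence)):
            raise ValueError("junction_offset must be strictly inside the sequence")

    @property
    def arm_lengths(self) -> tuple[int, int]:
        return (self.junction_offset, len(self.sequence) - self.junction_offset)


def build_junction_reference(
    call: FusionCall,
    genome: Mapping[str, str] | None = None,
    gene_model: GeneModel | None = None,
    config: ScreenConfig | None = None,
) -> JunctionRef:
    """Junction reference for one call.

    A junction sequence already carried by the call is returned verbatim.
    Otherwise arms are cut from the genome, strand-aware: the 5' arm ends at
    bp5 in the 5' gene's transcription orientation and the 3' arm starts at
    bp3 in the 3' gene's orientation.  Arms truncated by a contig end must
    still reach min_overhang.
    """
    config = config or ScreenConfig()
    if call.junction_seq is not None and call.junction_offset is not None:
        return JunctionRef(call.event_id, call.junction_seq, call.junction_offset)
    if genome is None:
        raise ValueError(f"{call.event_id}: no junction_seq and no genome to build one")

    def resolve_strand(gene: str, bp) -> str:
        if bp.strand is not None:
            return bp.strand
        if gene_model is not None and gene in gene_model:
            return gene_model.strand(gene)
        return "+"

    arm = config.arm_length
    arm5 = _genome_arm(genome, call.bp5, resolve_strand(call.gene5, call.bp5), arm, side=5)
    arm3 = _genome_arm(genome, call.bp3, resolve_strand(call.gene3, call.bp3), arm, side=3)
    for label, a in (("5'", arm5), ("3'", arm3)):
        if len(a) < config.min_overhang:
            raise ValueError(
                f"{call.event_id}: {label} arm truncated below min_overhang at contig end"
            )
    return JunctionRef(call.event_id, arm5 + arm3, len(arm5))


def _genome_arm(genome: Mapping[str, str], bp, strand: str, arm: int, side: int) -> str:
    seq = genome[bp.chromosome]
    pos0 = bp.position - 1  # 0-based
    # On +, the 5' arm is the window ending at bp (inclusive) and the 3' arm
    # starts at bp; on -, windows mirror and are reverse-complemented.
    if (side == 5) == (strand == "+"):
        piece = seq[max(0, pos0 - arm + 1) : pos0 + 1]
    else:
        piece = seq[pos0 : pos0 + arm]
    return piece if strand == "+" else revcomp(piece)


class JunctionIndex:
    """K-mer-seeded ungapped aligner over a set of junction references.

    Seeds are exact k-mers probed at fixed stride along each read (both
    orientations); hits are verified by a full-length Hamming comparison and
    the both-sides overhang rule.
    """

    def __init__(self, junctions: Sequence[JunctionRef], config: ScreenConfig | None = None):
        self.config = config or ScreenConfig()
        self.junctions = list(junctions)
        k = self.config.kmer_size
        self._seeds: dict[str, list[tuple[int, int]]] = {}
        for j_idx, jref in enumerate(self.junctions):
            seq = jref.sequence
            for pos in range(0, len(seq) - k + 1):
                self._seeds.setdefault(seq[pos : pos + k], []).append((j_idx, pos))

    def _candidate_offsets(self, read: str) -> set[tuple[int, int]]:
        k = self.config.kmer_size
        cands: set[tuple[int, int]] = set()
        if len(read) < k:
            return cands
        probes = list(range(0, len(read) - k + 1, k))
        if probes[-1] != len(read) - k:
            probes.append(len(read) - k)
        for p in probes:
            for j_idx, jpos in self._seeds.get(read[p : p + k], ()):
                cands.add((j_idx, jpos - p))
        return cands

    def _spans(self, j_idx: int, offset: int, read_len: int) -> bool:
        jref = self.junctions[j_idx]
        o = self.config.min_overhang
        return (
            offset >= 0
            and offset + read_len <= len(jref.sequence)
            and offset <= jref.junction_offset - o
            and offset + read_len >= jref.junction_offset + o
        )

    def spanning_hits(self, read: str) -> set[int]:
        """Indices of junctions this read (either orientation) spans."""
        hits: set[int] = set()
        for oriented in (read, revcomp(read)):
            for j_idx, offset in self._candidate_offsets(oriented):
                if j_idx in hits or not self._spans(j_idx, offset, len(oriented)):
                    continue
                window = self.junctions[j_idx].sequence[offset : offset + len(oriented)]
                if hamming_leq(oriented, window, self.config.max_mismatches):
                    hits.add(j_idx)
        return hits

    def count(self, reads: Iterable[str]) -> list[int]:
        """Spanning-read count per junction over a read set."""
        counts = [0] * len(self.junctions)
        for read in reads:
            for j_idx in self.spanning_hits(read):
                counts[j_idx] += 1
        return counts


def count_spanning_reads(
    junction: JunctionRef, reads: Iterable[str], config: ScreenConfig | None = None
) -> int:
    """Number of reads spanning one junction (both-sides overhang rule)."""
    return JunctionIndex([junction], config).count(reads)[0]


def screen_cohort(
    junctions: Sequence[JunctionRef],
    cohort_reads: Mapping[str, Iterable[str]],
    config: ScreenConfig | None = None,
) -> dict[str, dict[str, int]]:
    """Per-sample spanning counts: {sample_id: {event_id: count}}."""
    config = config or ScreenConfig()
    index = JunctionIndex(junctions, config)
    out: dict[str, dict[str, int]] = {}
    for sample_id, reads in cohort_reads.items():
        counts = index.count(reads)
        out[sample_id] = {
            jref.event_id: counts[i] for i, jref in enumerate(index.junctions)
        }
    return out


@dataclass
class PresenceCell:
    positives: int
    screened: int
    positive_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.positives > self.screened:
            raise ValueError("positives cannot exceed screened samples")

    @property
    def present(self) -> bool:
        return self.positives >= 1

    def __str__(self) -> str:
        return f"{self.positives}/{self.screened}"


@dataclass
class PresenceMatrix:
    """Events x cohorts table of spanning-read presence."""

    event_ids: list[str]
    cohort_ids: list[str]
    cells: dict[tuple[str, str], PresenceCell] = field(default_factory=dict)

    def cell(self, event_id: str, cohort_id: str) -> PresenceCell:
        return self.cells.get((event_id, cohort_id), PresenceCell(0, 0))

    def row(self, event_id: str) -> dict[str, PresenceCell]:
        return {c: self.cell(event_id, c) for c in self.cohort_ids}

    def present(self, event_id: str, cohort_id: str) -> bool:
        return self.cell(event_id, cohort_id).present

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {c: [str(self.cell(e, c)) for e in self.event_ids] for c in self.cohort_ids},
            index=self.event_ids,
        )


def assemble_presence_matrix(
    screen_results: Mapping[str, Mapping[str, Mapping[str, int]]],
    config: ScreenConfig | None = None,
    own_cohort: str | None = None,
) -> PresenceMatrix:
    """Build the presence matrix from per-cohort screen results.

    ``screen_results``: {cohort_id: {sample_id: {event_id: count}}}.  A sample
    is positive for an event when its spanning count reaches
    ``presence_min_reads``.  Positive sample ids are retained for the cohort
    named by ``own_cohort`` (or all cohorts when None).
    """
    config = config or ScreenConfig()
    cohort_ids = list(screen_results)
    if len(set(cohort_ids)) != len(cohort_ids):
        raise ValueError("duplicate cohort ids")
    event_ids: list[str] = []
    for per_sample in screen_results.values():
        for counts in per_sample.values():
            for eid in counts:
                if eid not in event_ids:
                    event_ids.append(eid)
    matrix = PresenceMatrix(event_ids, cohort_ids)
    for cohort_id, per_sample in screen_results.items():
        for eid in event_ids:
            positives = [
                sid
                for sid, counts in per_sample.items()
                if counts.get(eid, 0) >= config.presence_min_reads
            ]
            keep_ids = own_cohort is None or cohort_id == own_cohort
            matrix.cells[(eid, cohort_id)] = PresenceCell(
                len(positives),
                len(per_sample),
                tuple(sorted(positives)) if keep_ids else (),
            )
    return matrix
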