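"""Filter-rule semantics: boundaries, hand-checked examples, truth-manifest
recovery and cascade invariants."""

import numpy as np
import pytest

from conjoinscan._util import revcomp
from conjoinscan.filters import (
    Blacklist,
    FilterConfig,
    filter_blacklist,
    filter_flank_coverage,
    filter_genomic_match,
    filter_incidence,
    filter_junction_support,
    filter_shared_breakpoints,
    read_blacklist,
    run_cascade,
)
from conjoinscan.io import AlignmentIndex, Breakpoint, FusionCall


def call(eid, g5="A", g3="B", bp5=("1", 1000), bp3=("2", 2000), **kw):
    return FusionCall(eid, g5, g3, Breakpoint(*bp5), Breakpoint(*bp3), **kw)


def test_blacklist_pair_matching_is_unordered():
    cfg = FilterConfig(blacklist=Blacklist.from_pairs([("HBB", "HBA1")]))
    kept, removed = filter_blacklist(
        [call("e1", "HBB", "HBA1"), call("e2", "HBA1", "HBB"), call("e3", "X", "Y")], cfg
    )
    assert [e.event_id for e in removed] == ["e1", "e2"]
    assert [e.event_id for e in kept] == ["e3"]


def test_empty_blacklist_is_identity():
    events = [call("e1"), call("e2")]
    kept, removed = filter_blacklist(events, FilterConfig())
    assert kept == events and removed == []


def test_blacklist_regions_and_file_round_trip(tmp_path):
    path = tmp_path / "bl.tsv"
    path.write_text("HBB\tHBA1\nchr1\t999\t1100\n")  # BED region: 1-based 1000..1100
    bl = read_blacklist(path)
    cfg = FilterConfig(blacklist=bl)
    kept, removed = filter_blacklist(
        [call("in_region", bp5=("chr1", 1000)), call("outside", bp5=("chr1", 1101))], cfg
    )
    assert [e.event_id for e in removed] == ["in_region"]


def test_shared_breakpoint_across_gene_pairs_removes_all_sharers():
    events = [
        call("e1", "A", "B", bp5=("1", 1000), bp3=("2", 5)),
        call("e2", "A", "C", bp5=("1", 1000), bp3=("3", 6)),
        call("e3", "D", "E", bp5=("1", 1000), bp3=("4", 7)),
        call("e4", "F", "G", bp5=("9", 42), bp3=("5", 8)),
    ]
    kept, removed = filter_shared_breakpoints(events, FilterConfig())
    assert {e.event_id for e in removed} == {"e1", "e2", "e3"}
    assert [e.event_id for e in kept] == ["e4"]


def test_breakpoint_variants_of_one_gene_pair_are_retained():
    # same gene pair, two 3' breakpoints sharing the 5' coordinate: kept
    events = [
        call("v1", "SURF1", "MED22", bp5=("9", 133351836), bp3=("9", 133345252)),
        call("v2", "SURF1", "MED22", bp5=("9", 133351836), bp3=("9", 133346700)),
    ]
    kept, removed = filter_shared_breakpoints(events, FilterConfig())
    assert removed == [] and len(kept) == 2


def test_all_unique_breakpoints_identity():
    events = [call("e1"), call("e2", bp5=("1", 1001), bp3=("2", 2001))]
    kept, removed = filter_shared_breakpoints(events, FilterConfig())
    assert kept == events


GENOME = {"chr1": "ACGTTGCAGGTACCGATCGATTGCCGTAAGGCTAGCTTACGGATCCGTACGTAGCTAGCGGCATTACG" * 4}


def _genomic_call(eid, jseq):
    return call(eid, bp5=("chr1", 10), bp3=("chr1", 200), junction_seq=jseq,
                junction_offset=len(jseq) // 2)


def _mutate_at(seq, positions):
    chars = list(seq)
    for p in positions:
        chars[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[p]]
    return "".join(chars)


def brute_force_hamming_hit(query, genome, max_mm):
    """Oracle: sliding-window Hamming scan over both strands."""
    for oriented in (query, revcomp(query)):
        L = len(oriented)
        for seq in genome.values():
            for s in range(len(seq) - L + 1):
                window = seq[s : s + L]
                if sum(a != b for a, b in zip(oriented, window)) <= max_mm:
                    return True
    return False


def test_genomic_match_exact_substring_removed():
    jseq = GENOME["chr1"][30:90]
    cfg = FilterConfig()
    kept, removed = filter_genomic_match([_genomic_call("e1", jseq)], GENOME, cfg)
    assert [e.event_id for e in removed] == ["e1"]


def test_genomic_match_reverse_strand_removed():
    jseq = revcomp(GENOME["chr1"][30:90])
    kept, removed = filter_genomic_match([_genomic_call("e1", jseq)], GENOME, FilterConfig())
    assert removed


@pytest.mark.parametrize("n_mismatches,expect_removed", [(1, True), (2, True), (3, False)])
def test_genomic_match_mismatch_budget(n_mismatches, expect_removed):
    jseq = _mutate_at(GENOME["chr1"][40:110], list(range(n_mismatches)))
    assert brute_force_hamming_hit(jseq, GENOME, 2) == expect_removed  # oracle agrees
    kept, removed = filter_genomic_match([_genomic_call("e1", jseq)], GENOME, FilterConfig())
    assert bool(removed) == expect_removed


def test_genomic_match_chimeric_junction_kept():
    rng = np.random.default_rng(0)
    random_arm = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
    jseq = GENOME["chr1"][10:50] + random_arm
    assert not brute_force_hamming_hit(jseq, GENOME, 2)
    kept, removed = filter_genomic_match([_genomic_call("e1", jseq)], GENOME, FilterConfig())
    assert kept and not removed


def test_genomic_match_requires_junction_seq():
    with pytest.raises(ValueError, match="junction_seq"):
        filter_genomic_match([call("e1")], GENOME, FilterConfig())


def _uniform_index(depth5, depth3, pos5=500, pos3=2500, length=5000):
    """Depth exactly depth5 around pos5 and depth3 around pos3 (300bp blocks)."""
    index = AlignmentIndex({"chr1": length})
    for d, pos in ((depth5, pos5), (depth3, pos3)):
        for _ in range(d):
            index.add("chr1", pos - 150, pos + 150)
    return index.finalize()


@pytest.mark.parametrize("depth,kept_expected", [(10, True), (9, False)])
def test_flank_coverage_boundary(depth, kept_expected):
    index = _uniform_index(depth, 50)
    ev = call("e1", bp5=("chr1", 500), bp3=("chr1", 2500))
    kept, removed = filter_flank_coverage([ev], index, FilterConfig())
    assert bool(kept) == kept_expected


def test_flank_coverage_unknown_chromosome_errors():
    index = _uniform_index(10, 10)
    with pytest.raises(ValueError, match="absent from alignments"):
        filter_flank_coverage([call("e1", bp5=("chrZ", 5), bp3=("chr1", 2500))], index, FilterConfig())


@pytest.mark.parametrize("seed,linear,kept_expected", [(5, 95, True), (4, 96, False)])
def test_incidence_boundary(seed, linear, kept_expected):
    # 5 junction reads over 95 linear = exactly 5%: survives; 4/96 is removed
    index = _uniform_index(linear, linear)
    ev = call("e1", bp5=("chr1", 500), bp3=("chr1", 2500), seed_reads=seed)
    kept, removed = filter_incidence([ev], index, FilterConfig())
    assert bool(kept) == kept_expected


def test_incidence_no_evidence_removed():
    index = AlignmentIndex({"chr1": 5000}).finalize()
    ev = call("e1", bp5=("chr1", 500), bp3=("chr1", 2500), seed_reads=0)
    kept, removed = filter_incidence([ev], index, FilterConfig())
    assert removed == [ev]


def test_junction_support_requires_both_sides():
    jseq = "ACGTTGCAGGTACCGATCGA" + "TTGCCGTAAGGCTAGCTTAC"
    ev = call("e1", junction_seq=jseq, junction_offset=20)
    cfg = FilterConfig()
    spanning = jseq[8:32]  # 12 bases each side of the joint
    one_side = jseq[:20]  # 5' arm only
    kept, _ = filter_junction_support([ev], [spanning], cfg)
    assert kept
    kept, removed = filter_junction_support([ev], [one_side, one_side], cfg)
    assert removed


def test_junction_support_too_short_junction_errors():
    ev = call("e1", junction_seq="ACGTACGTAC", junction_offset=5)
    with pytest.raises(ValueError, match="min_overhang"):
        filter_junction_support([ev], [], FilterConfig())


# ---------------------------------------------------------------------------
# cascade on the synthetic bundle
# ---------------------------------------------------------------------------

def test_cascade_recovers_planted_events_exactly(full_cascade):
    bundle, _, survivors, report = full_cascade
    truth = bundle.manifest.true_event_ids()
    got = {s.event_id for s in survivors}
    assert got == truth  # precision = recall = 1
    assert report.n_raw == len(bundle.calls)
    assert report.n_survivors == len(truth)


def test_each_artifact_fails_exactly_its_designated_rule(full_cascade):
    bundle, _, _, report = full_cascade
    rule_for = {
        "blacklisted": "blacklist",
        "shared_breakpoint": "shared_breakpoint",
        "genomic_match": "genomic_match",
        "low_coverage": "flank_coverage",
        "low_incidence": "incidence",
        "no_junction_support": "junction_support",
    }
    for entry in bundle.manifest.artifacts:
        assert report.audit[entry["event_id"]] == [rule_for[entry["artifact_class"]]]


def test_audit_trail_complete(full_cascade):
    bundle, _, survivors, report = full_cascade
    survivor_ids = {s.event_id for s in survivors}
    for c in bundle.calls:
        if c.event_id in survivor_ids:
            assert c.event_id not in report.audit
        else:
            assert report.audit[c.event_id], c.event_id
    assert report.n_survivors + len(report.audit) == report.n_raw


def test_per_rule_fractions_are_independent(full_cascade):
    bundle, _, _, report = full_cascade
    n_artifacts = len(bundle.manifest.artifacts)
    assert sum(report.independent_counts.values()) == n_artifacts
    assert abs(sum(report.independent_fractions.values()) - n_artifacts / report.n_raw) < 1e-12
    assert sum(n for _, n in report.sequential_removals) + report.n_survivors == report.n_raw


def test_cascade_is_idempotent(full_cascade):
    bundle, config, survivors, _ = full_cascade
    again, report2 = run_cascade(
        survivors, bundle.genome, bundle.reads.alignments, config,
        reads=bundle.reads.sequences(), gene_model=bundle.gene_model,
    )
    assert [e.event_id for e in again] == [e.event_id for e in survivors]
    assert report2.audit == {}


def test_cascade_empty_input():
    genome = {"chr1": "ACGT" * 100}
    index = AlignmentIndex({"chr1": 400}).finalize()
    survivors, report = run_cascade([], genome, index, FilterConfig(), reads=[])
    assert survivors == [] and report.n_raw == 0 and report.n_survivors == 0
    assert all(n == 0 for n in report.independent_counts.values())


def test_report_serializes(full_cascade, tmp_path):
    import json

    _, _, _, report = full_cascade
    path = tmp_path / "report.json"
    report.to_json(path)
    payload = json.loads(path.read_text())
    assert payload["n_raw"] == report.n_raw
    assert set(payload["independent_fractions"]) == set(report.independent_fractions)
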