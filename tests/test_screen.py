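"""Junction construction, spanning-read counting (with a brute-force oracle),
cohort screening and presence-matrix assembly."""

import numpy as np
import pytest

from conjoinscan._util import revcomp
from conjoinscan.io import Breakpoint, FusionCall, Gene, GeneModel
from conjoinscan.screen import (
    JunctionRef,
    PresenceCell,
    ScreenConfig,
    assemble_presence_matrix,
    build_junction_reference,
    count_spanning_reads,
    screen_cohort,
)
from conjoinscan.simulate import simulate_cohort_reads

from conftest import small_params


def random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def test_existing_junction_returned_verbatim():
    c = FusionCall("e1", "A", "B", Breakpoint("1", 100), Breakpoint("2", 100),
                   junction_seq="ACGTACGTACGTACGTACGT", junction_offset=10)
    jref = build_junction_reference(c)
    assert jref.sequence == c.junction_seq and jref.junction_offset == 10


def test_plus_strand_junction_is_definitional():
    genome = {"1": random_seq(500, 1), "2": random_seq(500, 2)}
    cfg = ScreenConfig(arm_length=20)
    c = FusionCall("e1", "A", "B", Breakpoint("1", 100, "+"), Breakpoint("2", 300, "+"))
    jref = build_junction_reference(c, genome, None, cfg)
    # 5' arm: genome[bp5-arm+1..bp5]; 3' arm: genome[bp3..bp3+arm-1] (1-based)
    assert jref.sequence == genome["1"][80:100] + genome["2"][299:319]
    assert jref.junction_offset == 20


def test_minus_strand_arms_are_reverse_complemented():
    genome = {"1": random_seq(500, 3)}
    cfg = ScreenConfig(arm_length=15)
    c = FusionCall("e1", "A", "B", Breakpoint("1", 100, "-"), Breakpoint("1", 300, "-"))
    jref = build_junction_reference(c, genome, None, cfg)
    assert jref.sequence == revcomp(genome["1"][99:114]) + revcomp(genome["1"][285:300])


def test_strand_resolved_from_gene_model():
    genome = {"1": random_seq(500, 4)}
    model = GeneModel([Gene("A", "1", 50, 150, "-"), Gene("B", "1", 250, 350, "+")])
    c = FusionCall("e1", "A", "B", Breakpoint("1", 100), Breakpoint("1", 300))
    jref = build_junction_reference(c, genome, model, ScreenConfig(arm_length=15))
    assert jref.sequence[:15] == revcomp(genome["1"][99:114])


def test_arm_truncated_below_overhang_errors():
    genome = {"1": random_seq(100, 5)}
    c = FusionCall("e1", "A", "B", Breakpoint("1", 3, "+"), Breakpoint("1", 50, "+"))
    with pytest.raises(ValueError, match="truncated"):
        build_junction_reference(c, genome, None, ScreenConfig(arm_length=20))


def test_synthetic_junction_matches_generator(small_bundle):
    cfg = ScreenConfig(
        read_length=small_bundle.params.read_length,
        min_overhang=small_bundle.params.min_overhang,
    )
    for ev in small_bundle.events:
        if ev.klass != "cg":
            continue
        stripped = FusionCall(ev.event_id, ev.gene5, ev.gene3, ev.bp5, ev.bp3)
        jref = build_junction_reference(stripped, small_bundle.genome, small_bundle.gene_model, cfg)
        assert jref.sequence == ev.junction_seq
        assert jref.junction_offset == ev.junction_offset


def brute_force_spanning_count(junction: JunctionRef, reads, min_overhang=8, max_mm=0):
    """Oracle: enumerate every placement of every read on the junction."""
    total = 0
    jseq, off = junction.sequence, junction.junction_offset
    for read in reads:
        hit = False
        for oriented in (read, revcomp(read)):
            L = len(oriented)
            for s in range(len(jseq) - L + 1):
                if s > off - min_overhang or s + L < off + min_overhang:
                    continue
                if sum(a != b for a, b in zip(oriented, jseq[s : s + L])) <= max_mm:
                    hit = True
        total += hit
    return total


def test_one_side_read_never_counts():
    jseq = random_seq(136, 6)
    jref = JunctionRef("e1", jseq, 68)
    inside = jseq[0:60]  # read confined to the 5' arm
    assert count_spanning_reads(jref, [inside]) == 0
    short_overhang = jseq[10:74]  # crosses the joint with only 6 bases beyond it
    assert count_spanning_reads(jref, [short_overhang]) == 0


def test_centered_read_counts_once():
    jseq = random_seq(136, 7)
    jref = JunctionRef("e1", jseq, 68)
    read = jseq[30:106]
    assert count_spanning_reads(jref, [read]) == 1


def test_error_free_tiling_count_is_closed_form():
    """Tiling every start offset of a 76-mer on a 68/68 junction with 8 bp
    overhang: placements s with s <= 60 and s+76 >= 76, i.e. 61 reads."""
    jseq = random_seq(136, 8)
    jref = JunctionRef("e1", jseq, 68)
    reads = [jseq[s : s + 76] for s in range(0, 136 - 76 + 1)]
    count = count_spanning_reads(jref, reads)
    assert count == 76 - 2 * 8 + 1 == 61
    assert count == brute_force_spanning_count(jref, reads)


def test_spanning_count_matches_brute_force_on_random_reads():
    rng = np.random.default_rng(9)
    jseq = random_seq(136, 10)
    jref = JunctionRef("e1", jseq, 68)
    reads = []
    for _ in range(60):
        s = int(rng.integers(0, 61))
        reads.append(jseq[s : s + 76])
    for _ in range(40):  # random non-matching reads
        reads.append(random_seq(76, int(rng.integers(1e6))))
    cfg = ScreenConfig(max_mismatches=0)
    assert count_spanning_reads(jref, reads, cfg) == brute_force_spanning_count(jref, reads)


def test_reverse_complement_symmetry():
    jseq = random_seq(136, 11)
    jref = JunctionRef("e1", jseq, 68)
    reads = [jseq[s : s + 76] for s in range(0, 61, 7)]
    rc_jref = JunctionRef("e1", revcomp(jseq), 136 - 68)
    rc_reads = [revcomp(r) for r in reads]
    assert count_spanning_reads(jref, reads) == count_spanning_reads(rc_jref, rc_reads)


def test_mismatch_budget_in_screen():
    jseq = random_seq(136, 12)
    jref = JunctionRef("e1", jseq, 68)
    read = list(jseq[30:106])
    read[0], read[10], read[20] = "N", "N", "N"  # 3 mismatches
    assert count_spanning_reads(jref, ["".join(read)]) == 0
    read2 = list(jseq[30:106])
    read2[0], read2[10] = "N", "N"  # 2 mismatches: within budget
    assert count_spanning_reads(jref, ["".join(read2)]) == 1


def test_screen_cohort_and_monotonicity(small_bundle):
    b = small_bundle
    cg_events = [ev for ev in b.events if ev.klass == "cg"]
    target = cg_events[0]
    cfg = ScreenConfig(read_length=b.params.read_length)
    junctions = [JunctionRef(ev.event_id, ev.junction_seq, ev.junction_offset) for ev in cg_events]
    inclusion = {
        "AML": {
            "s1": [target.event_id], "s2": [target.event_id], "s3": [target.event_id],
            "s4": [], "s5": [],
        }
    }
    reads = simulate_cohort_reads(b.params, b.genome, b.gene_model, b.events, inclusion, seed=77)
    counts = screen_cohort(junctions, reads["AML"], cfg)
    positives = [s for s, per_event in counts.items() if per_event[target.event_id] > 0]
    assert sorted(positives) == ["s1", "s2", "s3"]
    # doubling reads never decreases counts
    doubled = {s: list(r) * 2 for s, r in reads["AML"].items()}
    counts2 = screen_cohort(junctions, doubled, cfg)
    for s in counts:
        for eid in counts[s]:
            assert counts2[s][eid] >= counts[s][eid]


def test_screen_cohort_no_reads_all_zero():
    jref = JunctionRef("e1", random_seq(136, 13), 68)
    counts = screen_cohort([jref], {"s1": [], "s2": []})
    assert counts == {"s1": {"e1": 0}, "s2": {"e1": 0}}


def test_presence_matrix_assembly():
    results = {
        "AML": {f"s{i}": {"e1": 1 if i <= 17 else 0} for i in range(1, 28)},
        "T-ALL": {f"t{i}": {"e1": 0} for i in range(1, 15)},
    }
    matrix = assemble_presence_matrix(results, own_cohort="AML")
    cell = matrix.cell("e1", "AML")
    assert str(cell) == "17/27" and cell.present
    assert not matrix.present("e1", "T-ALL")
    assert str(matrix.cell("e1", "T-ALL")) == "0/14"
    # positives recomputed from the per-sample tallies
    recount = sum(1 for counts in results["AML"].values() if counts["e1"] >= 1)
    assert cell.positives == recount


def test_presence_matrix_validations():
    with pytest.raises(ValueError):
        PresenceCell(5, 3)
    matrix = assemble_presence_matrix({"A": {"s": {"e": 0}}})
    assert not matrix.present("e", "A")
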