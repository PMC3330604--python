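"""Deletion calling, EDPE, and the two split-search strategies."""

import math

import numpy as np
import pytest

from partialalign import (
    METHOD_BINARY,
    METHOD_INCREMENTAL,
    STATUS_DISCORDANT,
    STATUS_NOT_CONVERGED,
    NoDeletionBetweenParts,
    ParameterError,
    Sequence,
    binary_partial_align,
    call_deletion,
    edpe,
    find_deletion,
    incremental_partial_align,
    make_query,
    smith_waterman,
    step_size,
    synthetic_reference,
    worked_example_analog,
)

from conftest import pick_clean_two_fragment_ref


# -- deletion interval (former mapping ends at b, latter starts at c) -------

@pytest.mark.parametrize("b,c,interval,length", [
    (1427, 2071, (1428, 2070), 643),  # the mtDNA worked example
    (10, 12, (11, 11), 1),            # smallest callable deletion
])
def test_call_deletion(b, c, interval, length):
    d = call_deletion(b, c)
    assert (d.start, d.end) == interval
    assert d.length == length == c - b - 1


def test_adjacent_mappings_signal_no_deletion():
    with pytest.raises(NoDeletionBetweenParts):
        call_deletion(10, 11)
    with pytest.raises(NoDeletionBetweenParts):
        call_deletion(10, 8)


@pytest.mark.parametrize("est,true,err", [(37, 27, 10), (27, 27, 0), (5, 9, 4)])
def test_edpe(est, true, err):
    assert edpe(est, true) == err


@pytest.mark.parametrize("i,k", [(1, 10), (2, 5), (3, 2), (4, 1), (5, 0)])
def test_step_size_halving_schedule_40bp(i, k):
    assert step_size(40, i) == k == 40 // 2 ** (i + 1)


# -- worked-example analog (27 + 13 bp fragments in a 500 bp reference) -----

@pytest.mark.parametrize("seed", [0, 1, 2])
def test_binary_reproduces_published_split_trace(seed, blosum):
    """The binary strategy must visit former lengths 20, 30, 25, 27 and
    stop with the exact boundary, exactly as in the published example
    (intermediate latter parts drop below min_length, by design)."""
    ref, query, truth = worked_example_analog(seed)
    res = binary_partial_align(query, ref, threshold=0.9, min_length=20, scheme=blosum)
    assert [s.former_length for s in res.trace] == [20, 30, 25, 27]
    assert [s.latter_length for s in res.trace] == [20, 10, 15, 13]
    assert res.boundary_estimate == 27
    assert edpe(res.boundary_estimate, truth.true_boundary) == 0
    assert res.deletion_ref_start == truth.former_ref_end + 1
    assert res.deletion_ref_end == truth.latter_ref_start - 1
    assert res.deletion_length == truth.true_deletion_length
    assert res.sw_calls == 1 + 2 * 4


def test_incremental_recovers_worked_example_boundary(blosum):
    """The incremental scan stops one base past the boundary when the
    threshold exceeds 27/28 (the ratio of the first overshooting
    prefix); 0.97 is the operating point that reproduces the published
    boundary of 27."""
    ref, query, truth = worked_example_analog(1)
    res = incremental_partial_align(query, ref, threshold=0.97, min_length=20, scheme=blosum)
    assert res.boundary_estimate == 27
    assert (res.former.ref_start, res.former.ref_end) == (
        truth.former_ref_start, truth.former_ref_end)
    assert (res.latter.ref_start, res.latter.ref_end) == (
        truth.latter_ref_start, truth.latter_ref_end)
    assert res.deletion_length == truth.true_deletion_length


def test_strategies_agree_on_worked_example(blosum):
    ref, query, _ = worked_example_analog(2)
    bi = binary_partial_align(query, ref, 0.9, 20, blosum)
    inc = incremental_partial_align(query, ref, 0.97, 20, blosum)
    assert bi.boundary_estimate == inc.boundary_estimate == 27


# -- exact recovery on guarded synthetic queries ----------------------------

def test_incremental_exact_recovery_and_interval(blosum):
    """With unique exact fragments, guarded junctions and a threshold
    just under 1, the incremental scan recovers the boundary and the
    deletion interval exactly: a prefix one base past the boundary can
    never reach ratio 1 (the flanking base disagrees and a 1-base gap
    detour costs more than any match gains)."""
    ref = synthetic_reference(6000, 99)
    rng = np.random.default_rng(12)
    for i in range(25):
        query, truth = make_query(ref, (60, 160), min_fragment=20, min_deletion=1500,
                                  rng=rng, guards=True, query_id=f"q{i}")
        res = incremental_partial_align(query, ref, threshold=0.999, min_length=20,
                                        scheme=blosum)
        assert res.boundary_estimate == truth.true_boundary
        assert res.deletion_ref_start == truth.former_ref_end + 1
        assert res.deletion_ref_end == truth.latter_ref_start - 1
        assert res.deletion_length == truth.true_deletion_length


def test_binary_search_dynamics_on_guarded_queries(blosum):
    """The binary walk moves by exactly the Eq.-style halving steps, every
    split sums to the query length, and a converged boundary equals the
    planted one whenever the step schedule can reach it.  (The fixed
    halving schedule cannot reach every offset, so convergence to the
    exact boundary is not universal -- the published benchmark itself
    reports nonzero mean error for this strategy.)"""
    ref = synthetic_reference(6000, 99)
    rng = np.random.default_rng(13)
    exact = 0
    for i in range(25):
        query, truth = make_query(ref, (60, 160), min_fragment=20, min_deletion=1500,
                                  rng=rng, guards=True, query_id=f"q{i}")
        lq = len(query)
        res = binary_partial_align(query, ref, threshold=0.999, min_length=20, scheme=blosum)
        former_lengths = [s.former_length for s in res.trace]
        assert former_lengths[0] == lq // 2
        for t, s in enumerate(res.trace):
            assert s.former_length + s.latter_length == lq
            assert s.step == step_size(lq, s.iteration)
            if t + 1 < len(res.trace):
                nxt = res.trace[t + 1].former_length
                moved = abs(nxt - s.former_length)
                assert moved == s.step or nxt in (1, lq - 1)  # clamped at the ends
        assert res.boundary_estimate in former_lengths
        if res.status == "deletion" and res.boundary_estimate == truth.true_boundary:
            exact += 1
            assert res.deletion_length == truth.true_deletion_length
    assert exact >= 12  # recovers the exact boundary for most queries


def test_sw_call_budgets(blosum):
    """Binary stays within its logarithmic SW-call budget; the
    incremental scan within its linear one (one call per candidate
    former length, plus the whole-query and latter-part runs)."""
    ref = synthetic_reference(6000, 99)
    rng = np.random.default_rng(14)
    tot_inc = tot_bin = 0
    for i in range(10):
        query, truth = make_query(ref, (100, 200), min_fragment=20, min_deletion=1500,
                                  rng=rng, guards=True, query_id=f"q{i}")
        lq = len(query)
        bi = binary_partial_align(query, ref, 0.999, 20, blosum)
        inc = incremental_partial_align(query, ref, 0.999, 20, blosum)
        assert bi.sw_calls <= 1 + 2 * (math.ceil(math.log2(lq)) + 1)
        assert inc.sw_calls <= lq - 20 + 2
        tot_inc += inc.sw_calls
        tot_bin += bi.sw_calls
    assert tot_bin < tot_inc


# -- documented conventions and edge cases ----------------------------------

def test_exact_substring_reports_no_deletion(blosum):
    ref = synthetic_reference(800, 5)
    query = Sequence("q", ref.residues[100:160])
    for fn in (incremental_partial_align, binary_partial_align):
        res = fn(query, ref, 0.9, 20, blosum)
        assert res.no_deletion and res.boundary_estimate is None
        assert res.former is None and res.latter is None


def test_spec_sized_synthetic_example(blosum):
    """query = ref[21..60] + ref[301..330] on a clean 500 bp reference:
    boundary 40 and deletion [61, 300] of length 240 at a near-1
    threshold (at looser thresholds the scan deliberately overshoots)."""
    ref, frag1, frag2, _ = pick_clean_two_fragment_ref(20, 500, (21, 60), (301, 330))
    query = Sequence("q", frag1 + frag2)
    res = incremental_partial_align(query, ref, threshold=0.999, min_length=20, scheme=blosum)
    assert res.boundary_estimate == 40
    assert (res.deletion_ref_start, res.deletion_ref_end) == (61, 300)
    assert res.deletion_length == 240


def test_reversed_fragments_flagged_discordant(blosum):
    """Latter part mapping upstream of the former part: flagged, no
    deletion interval invented."""
    ref, frag1, frag2, _ = pick_clean_two_fragment_ref(200, 500, (21, 60), (301, 330))
    query = Sequence("q", frag2 + frag1)  # latter fragment first
    res = incremental_partial_align(query, ref, threshold=0.999, min_length=20, scheme=blosum)
    assert res.status == STATUS_DISCORDANT
    assert res.deletion_length is None


def test_unmappable_latter_part_not_converged(blosum):
    """A query whose tail is drawn independently of the reference can
    never satisfy both parts at a high threshold: the binary strategy
    reports its best split with a not-converged status instead of
    raising."""
    ref = synthetic_reference(2000, 8)
    rng = np.random.default_rng(1234)
    tail = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
    query = Sequence("q", ref.residues[100:140] + tail)
    res = binary_partial_align(query, ref, 0.95, 20, blosum)
    assert res.status == STATUS_NOT_CONVERGED
    assert res.boundary_estimate is not None
    assert res.trace  # best-so-far split came from the recorded trace


def test_parameter_validation(blosum):
    ref = synthetic_reference(200, 1)
    short = Sequence("q", ref.residues[:30])
    with pytest.raises(ParameterError, match="shorter than"):
        incremental_partial_align(short, ref, 0.9, 20, blosum)
    with pytest.raises(ParameterError, match="threshold"):
        binary_partial_align(Sequence("q", ref.residues[:60]), ref, 1.5, 20, blosum)
    with pytest.raises(ParameterError, match="min_length"):
        binary_partial_align(Sequence("q", ref.residues[:60]), ref, 0.9, 0, blosum)
    with pytest.raises(ParameterError, match="unknown method"):
        find_deletion(Sequence("q", ref.residues[:60]), ref, method="bogus", scheme=blosum)


def test_eq1_interval_arithmetic_consistency(blosum):
    """For every called deletion, the two mapped spans plus the deletion
    span tile the reference interval [a, d]."""
    ref = synthetic_reference(6000, 99)
    rng = np.random.default_rng(15)
    seen = 0
    for i in range(10):
        query, _ = make_query(ref, (80, 160), min_fragment=20, min_deletion=1500,
                              rng=rng, guards=True, query_id=f"q{i}")
        res = binary_partial_align(query, ref, 0.999, 20, blosum)
        if res.deletion_length is None:
            continue
        a, b = res.former.ref_start, res.former.ref_end
        c, d = res.latter.ref_start, res.latter.ref_end
        assert res.deletion_length + (b - a + 1) + (d - c + 1) == d - a + 1
        seen += 1
    assert seen >= 5
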