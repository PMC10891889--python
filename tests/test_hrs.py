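"""Tandem-repeat arrays, imperfect palindromes and hr assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from baculoscribe.genome import CircularGenome, reverse_complement
from baculoscribe.hrs import (assemble_hrs, find_palindromes,
                              find_tandem_repeats, hr_report)
from baculoscribe.orfs import OrfFeature

import oracles


def _random_seq(seed, n, gc=0.45):
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))


def _unit(seed, n=112):
    return _random_seq(seed, n)


# ---------------------------------------------------------------------------
# tandem repeats

def test_three_exact_copies_recovered():
    unit = _unit(1)
    seq = _random_seq(2, 500) + unit * 3 + _random_seq(3, 500)
    arrays = find_tandem_repeats(seq)
    assert len(arrays) == 1
    a = arrays[0]
    assert a.period == 112
    assert a.n_units == 3
    assert a.start == 501 and a.end == 500 + 336
    assert all(i == 100.0 for i in a.identities)


def test_diverged_copies_recovered_with_high_identity():
    rng = np.random.default_rng(9)
    unit = _unit(4)
    copies = []
    for _ in range(4):
        cp = list(unit)
        for pos in rng.choice(112, size=6, replace=False):  # ~5% per copy
            cp[pos] = "ACGT"[(("ACGT".index(cp[pos])) + 1 + rng.integers(3)) % 4]
        copies.append("".join(cp))
    seq = _random_seq(5, 400) + "".join(copies) + _random_seq(6, 400)
    arrays = find_tandem_repeats(seq)
    assert len(arrays) == 1
    a = arrays[0]
    assert abs(a.period - 112) <= 2
    assert a.n_units == 4
    assert a.mean_identity >= 90.0


def test_random_sequence_yields_no_arrays_over_20_seeds():
    """Null behaviour: i.i.d. 10-kb sequences produce no tandem-array calls
    at the default thresholds (20 fixed seeds)."""
    for seed in range(20):
        assert find_tandem_repeats(_random_seq(100 + seed, 10_000)) == []


@pytest.mark.parametrize("period,copies", [(60, 3), (112, 2), (200, 4)])
def test_period_and_copy_recovery_across_scales(period, copies):
    rng = np.random.default_rng(period * 7 + copies)
    unit = _random_seq(period + copies, period)
    cps = []
    for _ in range(copies):
        cp = list(unit)
        n_mut = max(1, int(0.05 * period))
        for pos in rng.choice(period, size=n_mut, replace=False):
            cp[pos] = "ACGT"[int(rng.integers(4))]
        cps.append("".join(cp))
    seq = _random_seq(1, 300) + "".join(cps) + _random_seq(2, 300)
    arrays = find_tandem_repeats(seq)
    assert len(arrays) == 1
    assert abs(arrays[0].period - period) <= 2
    assert arrays[0].n_units == copies


def test_too_short_sequence_returns_empty():
    assert find_tandem_repeats("ACGT" * 10) == []


# ---------------------------------------------------------------------------
# palindromes

def test_perfect_palindrome_aaaatttt():
    pals = find_palindromes("AAAATTTT", min_arm=4)
    assert len(pals) == 1
    p = pals[0]
    assert (p.arm_len, p.mismatches, p.gap, p.span) == (4, 0, 0, 8)


def test_homopolymer_has_no_palindrome():
    assert find_palindromes("A" * 60, min_arm=4) == []


def test_palindrome_strand_symmetry():
    seq = _random_seq(11, 300)
    fwd = find_palindromes(seq, min_arm=6, max_gap=4, max_mismatch=2)
    rev = find_palindromes(reverse_complement(seq), min_arm=6, max_gap=4,
                           max_mismatch=2)
    n = len(seq)
    fwd_keys = sorted((p.start, p.end, p.arm_len, p.mismatches) for p in fwd)
    # map reverse-strand coordinates back: pos i -> n + 1 - i
    rev_keys = sorted((n + 1 - p.end, n + 1 - p.start, p.arm_len,
                       p.mismatches) for p in rev)
    assert fwd_keys == rev_keys


@settings(max_examples=20)
@given(st.integers(0, 10_000))
def test_palindromes_match_bruteforce_oracle(seed):
    seq = _random_seq(seed, 200)
    got = {(p.start - 1, p.end - 1, p.arm_len, p.mismatches, p.gap)
           for p in find_palindromes(seq, min_arm=5, max_gap=3,
                                     max_mismatch=2)}
    want = oracles.brute_palindromes(seq, min_arm=5, max_gap=3,
                                     max_mismatch=2)
    assert got == want


# ---------------------------------------------------------------------------
# hr assembly

def _planted_genome(small_genome):
    return small_genome


def test_array_without_palindromic_core_rejected():
    # tandem copies of a pyrimidine-only unit cannot form an inverted repeat
    unit = "".join(np.random.default_rng(3).choice(["C", "T"], size=112))
    seq = _random_seq(1, 400) + unit * 3 + _random_seq(2, 400)
    g = CircularGenome(id="g", sequence=seq)
    arrays = find_tandem_repeats(seq)
    assert arrays, "tandem array itself must be detected"
    assert assemble_hrs(arrays, g) == []


def test_planted_hrs_assembled_with_names_in_genome_order(small_genome):
    genome, truth, _ = small_genome
    hrs = assemble_hrs(find_tandem_repeats(genome.sequence), genome)
    assert [h.name for h in hrs] == ["hr1", "hr2", "hr3"]
    for h in hrs:
        t = truth.hr_coords[h.name]
        assert abs(h.start - t["start"]) <= 10
        assert abs(h.end - t["end"]) <= 10
        assert len(h.units) == t["copies"]
        assert len(h.consensus) == t["period"]
        # palindromic core sits in the central third of the unit
        c = h.palindrome.center - 0.5
        assert len(h.consensus) / 3 <= c <= 2 * len(h.consensus) / 3
        assert h.palindrome.span >= 20


def test_assemble_empty_input_and_mismatch_monotonicity(small_genome):
    genome, _, _ = small_genome
    assert assemble_hrs([], genome) == []
    arrays = find_tandem_repeats(genome.sequence)
    lax = {(h.start, h.end) for h in assemble_hrs(arrays, genome,
                                                  max_mismatch=3)}
    strict = {(h.start, h.end) for h in assemble_hrs(arrays, genome,
                                                     max_mismatch=0)}
    assert strict <= lax


def test_hr_spans_do_not_overlap(small_genome):
    genome, _, _ = small_genome
    hrs = assemble_hrs(find_tandem_repeats(genome.sequence), genome)
    spans = sorted((h.start, h.end) for h in hrs)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 < s2


# ---------------------------------------------------------------------------
# report / flanks

def _orf(tag, start, end, strand="+"):
    return OrfFeature(locus_tag=tag, start=start, end=end, strand=strand,
                      length_aa=(end - start + 1) // 3 - 1 if end > start else 60,
                      frame=0, translation="")


def test_flanking_orfs_in_intergenic_gap(small_genome):
    genome, truth, _ = small_genome
    from baculoscribe.orfs import assign_locus_tags, find_orfs
    orfs = assign_locus_tags(find_orfs(genome, 50))
    hrs = assemble_hrs(find_tandem_repeats(genome.sequence), genome)
    rows = hr_report(hrs, orfs, genome.length)
    by_tag = {o.locus_tag: o for o in orfs}
    for row in rows:
        up = by_tag[row["flank_upstream"]]
        down = by_tag[row["flank_downstream"]]
        assert (row["start"] - up.end) % genome.length < genome.length / 4
        assert (down.start - row["end"]) % genome.length < genome.length / 4
        assert row["alignment"].count("\n") >= 2 * row["n_units"]


def test_flanks_computed_circularly_for_origin_spanning_hr():
    """An hr placed across the origin picks its neighbours through the wrap."""
    from baculoscribe.hrs import HrLocus, Palindrome
    hr = HrLocus(name="hr1", start=980, end=30, units=[], consensus="A" * 50,
                 palindrome=Palindrome(center=25, arm_len=10, mismatches=0,
                                       gap=0), at_percent=50.0)
    orfs = [_orf("before", 700, 960), _orf("after", 40, 300)]
    rows = hr_report([hr], orfs, genome_length=1000)
    assert rows[0]["flank_upstream"] == "before"
    assert rows[0]["flank_downstream"] == "after"
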