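"""Circular six-frame ORF prediction, overlap resolution and genome stats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from baculoscribe.genome import CircularGenome, extract_subsequence, reverse_complement
from baculoscribe.orfs import (OrfFeature, find_orfs, genome_stats,
                               mask_hr_orfs, resolve_overlaps, classify_orfs)
from baculoscribe.hrs import HrLocus

import oracles


def _orf(tag, start, end, strand="+", aa=None, L=None):
    if aa is None:
        span = end - start + 1 if end >= start else L - start + 1 + end
        aa = span // 3 - 1
    return OrfFeature(locus_tag=tag, start=start, end=end, strand=strand,
                      length_aa=aa, frame=0, translation="")


def test_no_start_codon_no_orfs():
    g = CircularGenome(id="g", sequence="C" * 600)
    assert find_orfs(g, min_aa=50) == []


def test_short_genome_returns_empty():
    g = CircularGenome(id="g", sequence="ATGAAATAA")
    assert find_orfs(g, min_aa=50) == []


def test_planted_orf_recovered_and_matches_bruteforce():
    rng = np.random.default_rng(42)
    bg = "".join("ACGT"[i] for i in rng.integers(0, 4, 4000))
    insert = "ATG" + "GCA" * 59 + "TAA"  # 60 codons incl start, 60 aa
    seq = bg[:1000] + insert + bg[1000:]
    g = CircularGenome(id="g", sequence=seq)
    found = find_orfs(g, min_aa=50)
    keys = {(o.start, o.end, o.strand, o.length_aa) for o in found}
    # the planted stop anchors an ORF of at least the planted length (the
    # most-upstream in-frame ATG may extend it into the random background)
    planted = [k for k in keys
               if k[1] == 1000 + len(insert) and k[2] == "+" and k[3] >= 60]
    assert len(planted) == 1
    assert keys == oracles.brute_orfs(seq, min_aa=50)


def test_origin_spanning_orf_reported_once():
    rng = np.random.default_rng(7)
    bg = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
    orf = "ATG" + "GCT" * 80 + "TGA"
    # place the ORF so its ATG sits 30 bp before the origin
    seq = orf[30:] + bg[: 2000 - len(orf)] + orf[:30]
    g = CircularGenome(id="g", sequence=seq)
    L = g.length
    spans = {(o.start, o.end) for o in find_orfs(g, min_aa=50)
             if o.end < o.start}
    # the planted wrap ORF appears exactly once, with circular coordinates
    assert (L - 29, len(orf) - 30) in spans
    assert {(x.start, x.end, x.strand, x.length_aa) for x in find_orfs(g, 50)} \
        == oracles.brute_orfs(seq, min_aa=50)


@settings(max_examples=15)
@given(st.integers(0, 10_000))
def test_find_orfs_matches_bruteforce_on_random_circles(seed):
    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 900))
    g = CircularGenome(id="g", sequence=seq)
    got = {(o.start, o.end, o.strand, o.length_aa)
           for o in find_orfs(g, min_aa=20)}
    assert got == oracles.brute_orfs(seq, min_aa=20, circular=True)


def test_reverse_complement_invariance():
    rng = np.random.default_rng(3)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1500))
    g = CircularGenome(id="g", sequence=seq)
    rc = CircularGenome(id="rc", sequence=reverse_complement(seq))
    L = len(seq)
    fwd = {(o.start, o.end, o.strand, o.length_aa) for o in find_orfs(g, 30)}
    mirrored = {(L - e + 1, L - s + 1, "-" if st_ == "+" else "+", aa)
                for s, e, st_, aa in fwd}
    rev = {(o.start, o.end, o.strand, o.length_aa) for o in find_orfs(rc, 30)}
    assert mirrored == rev


def test_rotation_invariance():
    from baculoscribe.genome import rotate_to_origin
    rng = np.random.default_rng(4)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1200))
    g = CircularGenome(id="g", sequence=seq)
    L = len(seq)
    shift = 321
    rot = rotate_to_origin(g, shift + 1)
    base = {(o.start, o.end, o.strand, o.length_aa) for o in find_orfs(g, 25)}
    unrot = {((s - 1 + shift) % L + 1, (e - 1 + shift) % L + 1, st_, aa)
             for s, e, st_, aa in
             ((o.start, o.end, o.strand, o.length_aa) for o in find_orfs(rot, 25))}
    assert base == unrot


def test_translations_consistent_with_coordinates():
    rng = np.random.default_rng(5)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1500))
    g = CircularGenome(id="g", sequence=seq)
    from Bio.Seq import Seq
    for o in find_orfs(g, 25):
        cds = extract_subsequence(g, o.start, o.end, o.strand)
        assert str(Seq(cds[:-3]).translate()) == o.translation
        assert o.translation.startswith("M")
        assert "*" not in o.translation


# ---------------------------------------------------------------------------
# overlap resolution

def test_overlap_at_exactly_75bp_keeps_both():
    a = _orf("a", 1, 300)
    b = _orf("b", 226, 500)   # overlap 226..300 = 75 bp
    out = resolve_overlaps([a, b], genome_length=1000)
    assert [o.locus_tag for o in out] == ["a", "b"]


def test_overlap_above_75bp_drops_smaller():
    big = _orf("big", 1, 903)      # 300 aa
    small = _orf("small", 784, 966)  # 60 aa, overlap 120 bp
    out = resolve_overlaps([big, small], genome_length=2000)
    assert [o.locus_tag for o in out] == ["big"]


def test_conserved_homolog_smaller_orf_retained():
    big = _orf("big", 1, 903)
    small = _orf("small", 784, 966)
    out = resolve_overlaps([big, small], genome_length=2000,
                           homolog_hits={"small": True})
    assert [o.locus_tag for o in out] == ["big", "small"]


def test_resolve_overlaps_idempotent_and_circular():
    orfs = [_orf("a", 900, 150, L=1000), _orf("b", 1, 120),
            _orf("c", 500, 650), _orf("d", 640, 800)]
    once = resolve_overlaps(orfs, genome_length=1000)
    twice = resolve_overlaps(once, genome_length=1000)
    assert [o.locus_tag for o in once] == [o.locus_tag for o in twice]


def test_equal_length_tie_prefers_plus_strand():
    a = _orf("minus", 1, 300, strand="-")
    b = _orf("plus", 100, 399, strand="+")
    out = resolve_overlaps([a, b], genome_length=1000)
    assert [o.locus_tag for o in out] == ["plus"]


# ---------------------------------------------------------------------------
# hr masking

def _hr(start, end):
    return HrLocus(name="hr", start=start, end=end, units=[], consensus="",
                   palindrome=None, at_percent=0.0)


def test_orf_inside_hr_removed_boundary_overlap_kept():
    orfs = [_orf("inside", 120, 320), _orf("straddle", 90, 210),
            _orf("outside", 600, 800)]
    out = mask_hr_orfs(orfs, [_hr(100, 400)], genome_length=1000)
    assert [o.locus_tag for o in out] == ["straddle", "outside"]


def test_mask_with_no_hrs_is_identity():
    orfs = [_orf("a", 1, 300)]
    assert mask_hr_orfs(orfs, [], genome_length=1000) == orfs


# ---------------------------------------------------------------------------
# statistics and classification

def test_gc_percent_simple_cases():
    assert genome_stats(CircularGenome(id="g", sequence="ATGC"), []).gc_percent == 50.0
    assert genome_stats(CircularGenome(id="g", sequence="ATAT"), []).gc_percent == 0.0


def test_gc_excludes_ambiguous_bases():
    st_ = genome_stats(CircularGenome(id="g", sequence="ATGCNNNN"), [])
    assert st_.gc_percent == 50.0


def test_coding_fraction_union_counts_overlap_once():
    g = CircularGenome(id="g", sequence="A" * 1000)
    orfs = [_orf("a", 1, 300), _orf("b", 201, 500, strand="-")]
    st_ = genome_stats(g, orfs)
    assert st_.coding_fraction_percent == pytest.approx(50.0)
    assert st_.forward_count == 1 and st_.reverse_count == 1


def test_classify_with_empty_references_all_unique():
    orfs = [_orf("a", 1, 300)]
    orfs[0].translation = "M" + "AGCT" * 30
    with pytest.warns(UserWarning):
        out = classify_orfs(orfs, {})
    assert all(o.annotation_class == "unique" for o in out)


def test_classify_planted_homologs(small_genome):
    """Five reference proteins copied from the proteome are recovered as
    core-class RBH matches; everything else stays unique."""
    genome, truth, _ = small_genome
    orfs = find_orfs(genome, 50)
    from baculoscribe.orfs import assign_locus_tags
    orfs = assign_locus_tags(orfs)
    chosen = [o for o in orfs if o.length_aa >= 100][:5]
    refs = {"core": {f"ref_{i}": o.translation for i, o in enumerate(chosen)}}
    out = classify_orfs(orfs, refs)
    classed = {o.locus_tag for o in out if o.annotation_class == "core"}
    assert classed == {o.locus_tag for o in chosen}
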