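"""RBH homology, parity plots, whole-genome identity, supermatrix export."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from baculoscribe.comparative import (HomologPair, concatenate_core_alignments,
                                      core_gene_check, local_protein_align,
                                      parity_points, reciprocal_best_hits,
                                      whole_genome_identity)
from baculoscribe.genome import CircularGenome
from baculoscribe.synthetic import make_ortholog_pair
from baculoscribe import _align

import oracles

AAS = "ACDEFGHIKLMNPQRSTVWY"


def _protein(rng, n):
    return "".join(rng.choice(AAS) for _ in range(n))


# ---------------------------------------------------------------------------
# local protein alignment

def test_self_alignment_full_identity():
    p = "MKVLLAGRRSDE" * 5
    score, ident = local_protein_align(p, p)
    assert ident == 100.0
    assert score > 0


def test_local_alignment_covers_shared_prefix():
    rng = random.Random(1)
    core = "MKVWE" * 6
    _, ident = local_protein_align(core, core + _protein(rng, 40))
    assert ident == 100.0


def test_empty_protein_rejected():
    with pytest.raises(ValueError):
        local_protein_align("", "MKV")


@settings(max_examples=25)
@given(st.integers(0, 10_000))
def test_local_score_matches_bruteforce_dp(seed):
    rng = random.Random(seed)
    p1 = _protein(rng, rng.randint(3, 30))
    p2 = _protein(rng, rng.randint(3, 30))
    score, _ = local_protein_align(p1, p2)
    assert score == pytest.approx(oracles.local_blosum_score(p1, p2))


# ---------------------------------------------------------------------------
# reciprocal best hits

def test_identical_proteomes_pair_one_to_one():
    rng = random.Random(2)
    proteome = {f"g{i:02d}": _protein(rng, 150) for i in range(8)}
    pairs = reciprocal_best_hits(proteome, dict(proteome))
    assert {(p.locus_a, p.locus_b) for p in pairs} == \
        {(k, k) for k in proteome}


def test_shuffled_decoys_yield_no_pairs():
    """Null calibration: residue-shuffled proteomes never reach the RBH
    score threshold (fixed seeds)."""
    for seed in (0, 1, 2):
        pa, pb, _ = make_ortholog_pair(8, 100.0, seed=200 + seed, n_decoys=0)
        rng = random.Random(seed)
        shuffled = {k: "".join(rng.sample(v, len(v))) for k, v in pb.items()}
        assert reciprocal_best_hits(pa, shuffled) == []


def test_planted_orthologs_recovered_exactly():
    pa, pb, truth = make_ortholog_pair(40, 60.0, seed=2, n_decoys=20)
    pairs = reciprocal_best_hits(pa, pb)
    assert {(p.locus_a, p.locus_b) for p in pairs} == set(truth.items())
    assert len(pairs) == 40


def test_rbh_symmetric():
    pa, pb, _ = make_ortholog_pair(10, 70.0, seed=4, n_decoys=5)
    fwd = {(p.locus_a, p.locus_b) for p in reciprocal_best_hits(pa, pb)}
    rev = {(p.locus_b, p.locus_a) for p in reciprocal_best_hits(pb, pa)}
    assert fwd == rev
    # one-to-one
    assert len({a for a, _ in fwd}) == len(fwd)
    assert len({b for _, b in fwd}) == len(fwd)


def test_empty_proteome_rejected():
    with pytest.raises(ValueError):
        reciprocal_best_hits({}, {"a": "MKV"})


# ---------------------------------------------------------------------------
# parity

def _self_pairs(tags):
    return [HomologPair(locus_a=t, locus_b=t, score=100.0, identity=100.0)
            for t in tags]


def test_self_comparison_is_diagonal_rho_one():
    tags = [f"g{i}" for i in range(20)]
    points, rho = parity_points(_self_pairs(tags), tags, tags)
    assert rho == 1.0
    assert all(p.rank_a == p.rank_b for p in points)


def test_reversed_order_rho_minus_one():
    tags = [f"g{i}" for i in range(20)]
    _, rho = parity_points(_self_pairs(tags), tags, tags[::-1])
    assert rho == -1.0


def test_inverted_block_shows_two_collinear_segments():
    tags = [f"g{i}" for i in range(30)]
    rearranged = tags[:10] + tags[10:20][::-1] + tags[20:]
    points, rho = parity_points(_self_pairs(tags), tags, rearranged)
    diag = [p for p in points if p.rank_a == p.rank_b]
    anti = [p for p in points if p.rank_a + p.rank_b == 31]
    assert len(diag) == 20 and len(anti) == 10
    assert 0 < rho < 1


# ---------------------------------------------------------------------------
# core-gene presence

def test_core_check_absent_and_identity_cases():
    rng = random.Random(7)
    refs = {f"fam{i:02d}": _protein(rng, 180) for i in range(10)}
    unrelated = {f"x{i}": _protein(rng, 180) for i in range(10)}
    _, n_absent = core_gene_check(unrelated, refs)
    assert n_absent == 0
    presence, n = core_gene_check(
        {f"q{i}": s for i, s in enumerate(refs.values())}, refs)
    assert n == 10 and all(presence.values())


def test_core_check_requires_references():
    with pytest.raises(ValueError):
        core_gene_check({"a": "MKV"}, {})


# ---------------------------------------------------------------------------
# whole-genome identity

def test_identity_of_genome_with_itself_is_100():
    g = CircularGenome(id="g", sequence="ACGTTGCA" * 50)
    assert whole_genome_identity(g, g) == 100.0


def test_identity_of_disjoint_homopolymers_is_0():
    a = CircularGenome(id="a", sequence="AAAA")
    b = CircularGenome(id="b", sequence="TTTT")
    assert whole_genome_identity(a, b) == 0.0


def test_identity_symmetric_and_bounded():
    """Score is exactly symmetric; identity is symmetric up to the choice
    among equally-optimal alignments, which is tight for related pairs."""
    rng = np.random.default_rng(3)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
    mutated = list(seq)
    for p in rng.choice(400, size=40, replace=False):
        mutated[p] = "ACGT"[int(rng.integers(4))]
    del mutated[200:210]
    a = CircularGenome(id="a", sequence=seq)
    b = CircularGenome(id="b", sequence="".join(mutated))
    sab = _align.score_global(a.sequence, b.sequence, 5, -4, -16, -4)
    sba = _align.score_global(b.sequence, a.sequence, 5, -4, -16, -4)
    assert sab == sba
    ab = whole_genome_identity(a, b)
    ba = whole_genome_identity(b, a)
    assert ab == pytest.approx(ba, abs=0.3)
    assert 0.0 <= ab <= 100.0


@settings(max_examples=20)
@given(st.integers(0, 10_000))
def test_linear_space_score_equals_quadratic_oracle(seed):
    """Divide-and-conquer alignment reproduces the full-matrix Gotoh score
    (stretcher scoring) on fuzzed related pairs up to ~250 bp."""
    rng = random.Random(seed)
    n = rng.randint(30, 250)
    a = "".join(rng.choice("ACGT") for _ in range(n))
    b = list(a)
    for _ in range(rng.randint(0, n // 5)):
        p = rng.randrange(len(b))
        op = rng.random()
        if op < 0.5:
            b[p] = rng.choice("ACGT")
        elif op < 0.75:
            b.insert(p, rng.choice("ACGT"))
        elif len(b) > 1:
            del b[p]
    b = "".join(b)
    aa, bb, score = _align.align_global(a, b, 5, -4, -16, -4)
    assert score == pytest.approx(
        oracles.gotoh_score(a, b, 5, -4, -16, -4))
    assert aa.replace("-", "") == a and bb.replace("-", "") == b


# ---------------------------------------------------------------------------
# supermatrix

def test_concatenation_widths_and_partitions():
    fams = {"famA": {"t1": "A" * 10, "t2": "C" * 10},
            "famB": {"t1": "D" * 20, "t2": "E" * 20}}
    sm, parts = concatenate_core_alignments(fams)
    assert len(sm["t1"]) == 30
    assert parts == [("famA", 1, 10), ("famB", 11, 30)]


def test_single_family_is_identity():
    fams = {"famA": {"t1": "MKV", "t2": "MRV"}}
    sm, parts = concatenate_core_alignments(fams)
    assert sm == fams["famA"]
    assert parts == [("famA", 1, 3)]


def test_taxon_mismatch_raises_with_names():
    fams = {"famA": {"t1": "MKV", "t2": "MRV"},
            "famB": {"t1": "MKV", "t3": "MRV"}}
    with pytest.raises(ValueError, match="famB"):
        concatenate_core_alignments(fams)


def test_partitions_tile_every_column_once():
    rng = random.Random(9)
    taxa = [f"t{i}" for i in range(5)]
    fams = {f"fam{i:02d}": {t: _protein(rng, rng.randint(5, 30)) for t in taxa}
            for i in range(38)}
    for aln in fams.values():  # pad families to equal width per family
        width = max(len(s) for s in aln.values())
        for t in aln:
            aln[t] = aln[t].ljust(width, "-")
    sm, parts = concatenate_core_alignments(fams)
    covered = []
    for _, s, e in parts:
        covered.extend(range(s, e + 1))
    total = len(next(iter(sm.values())))
    assert covered == list(range(1, total + 1))
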