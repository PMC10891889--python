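"""Kimura 2-parameter distances and the baculovirus species-demarcation rule.

The K2P model distinguishes transitions (A<->G, C<->T; proportion P) from
transversions (proportion Q) and estimates the per-site substitution
distance

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

Gap and N sites are excluded pairwise ("treated as missing data");
substitution rates among sites are uniform.  Pairs of the polh / lef-8 /
lef-9 marker genes with d > 0.05 substitutions/site on every marker indicate
distinct baculovirus species.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from . import _align

__all__ = ["AlignedPair", "K2PResult", "UndefinedDistanceError",
           "global_align_pair", "k2p_distance", "demarcation",
           "distance_matrix", "DEMARCATION_THRESHOLD"]

DEMARCATION_THRESHOLD = 0.05

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = set("ACGT")
_MISSING = set("N-")


class UndefinedDistanceError(ValueError):
    """No comparable sites remain after pairwise deletion."""


@dataclass
class AlignedPair:
    """Two gapped DNA strings of equal length."""

    seq_a: str
    seq_b: str
    source_gene: str = "other"   # polh | lef8 | lef9 | other

    def __post_init__(self):
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences must have equal length")
        alphabet = _BASES | _MISSING
        bad = (set(self.seq_a) | set(self.seq_b)) - alphabet
        if bad:
            raise ValueError(f"alignment contains non-DNA characters {sorted(bad)!r}")


@dataclass
class K2PResult:
    """Transition/transversion proportions and the K2P distance."""

    P: float
    Q: float
    n_sites: int
    distance: float
    defined: bool


def global_align_pair(a: str, b: str, match: float = 5.0,
                      mismatch: float = -4.0, gap_open: float = -10.0,
                      gap_extend: float = -0.5,
                      source_gene: str = "other") -> AlignedPair:
    """Optimal end-to-end affine-gap alignment of two marker-gene sequences.

    Deterministic tie-breaking: diagonal over gap, then gap in ``seq_a``.
    A gap of length L scores ``gap_open + (L-1)*gap_extend``.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aa, bb, _ = _align.align_global(a, b, match=match, mismatch=mismatch,
                                    gap_open=gap_open, gap_extend=gap_extend)
    return AlignedPair(seq_a=aa, seq_b=bb, source_gene=source_gene)


def k2p_distance(pair: AlignedPair) -> K2PResult:
    """K2P distance with pairwise deletion of gap/N sites.

    Raises :class:`UndefinedDistanceError` when no sites remain; returns
    ``defined=False`` (distance NaN) when the distance saturates, i.e.
    ``1 - 2P - Q <= 0`` or ``1 - 2Q <= 0``.
    """
    ts = tv = n = 0
    for x, y in zip(pair.seq_a, pair.seq_b):
        if x not in _BASES or y not in _BASES:
            continue
        n += 1
        if x == y:
            continue
        if (x, y) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise UndefinedDistanceError(
            "no comparable sites after pairwise deletion")
    P, Q = ts / n, tv / n
    t1 = 1.0 - 2.0 * P - Q
    t2 = 1.0 - 2.0 * Q
    if t1 <= 0.0 or t2 <= 0.0:
        return K2PResult(P=P, Q=Q, n_sites=n, distance=math.nan, defined=False)
    d = -0.5 * math.log(t1 * math.sqrt(t2))
    return K2PResult(P=P, Q=Q, n_sites=n, distance=d, defined=True)


def demarcation(results: dict, threshold: float = DEMARCATION_THRESHOLD) -> dict:
    """Apply the species-demarcation rule to per-marker K2P results.

    ``results`` maps a marker name (polh/lef8/lef9) to a K2PResult or a bare
    distance.  Verdict: ``novel`` iff every provided marker distance exceeds
    ``threshold``; ``not_novel`` iff every distance is <= threshold;
    ``inconclusive`` otherwise (mixed or undefined).  Missing canonical
    markers are reported alongside the verdict.
    """
    if not results:
        raise ValueError("demarcation requires at least one marker distance")
    dists = {}
    undefined = []
    for gene, res in results.items():
        d = res.distance if isinstance(res, K2PResult) else float(res)
        if isinstance(res, K2PResult) and not res.defined:
            undefined.append(gene)
        else:
            dists[gene] = d
    missing = [g for g in ("polh", "lef8", "lef9") if g not in results]
    if undefined or not dists:
        verdict = "inconclusive"
    elif all(d > threshold for d in dists.values()):
        verdict = "novel"
    elif all(d <= threshold for d in dists.values()):
        verdict = "not_novel"
    else:
        verdict = "inconclusive"
    return {"verdict": verdict, "threshold": threshold,
            "distances": dists, "undefined_markers": undefined,
            "missing_markers": missing}


def distance_matrix(seqs: dict, source_gene: str = "other", **align_kwargs):
    """All-pairs alignment + K2P for a named collection of marker sequences.

    Returns ``(names, matrix)`` where ``matrix[i][j]`` is a K2PResult
    (zero-distance results on the diagonal); symmetric by construction.
    """
    names = list(seqs)
    if len(names) < 2:
        raise ValueError("distance_matrix requires at least two sequences")
    n = len(names)
    mat = [[None] * n for _ in range(n)]
    for i in range(n):
        mat[i][i] = K2PResult(P=0.0, Q=0.0, n_sites=len(seqs[names[i]]),
                              distance=0.0, defined=True)
    for i, j in itertools.combinations(range(n), 2):
        pair = global_align_pair(seqs[names[i]], seqs[names[j]],
                                 source_gene=source_gene, **align_kwargs)
        res = k2p_distance(pair)
        mat[i][j] = mat[j][i] = res
    return names, mat


def write_phylip_matrix(names, mat, path: str) -> str:
    """Square PHYLIP-format distance matrix (NaN for undefined distances)."""
    with open(path, "w") as fh:
        fh.write(f"{len(names)}\n")
        for i, name in enumerate(names):
            vals = " ".join(f"{(mat[i][j].distance):.6f}" for j in range(len(names)))
            fh.write(f"{name[:10]:<10} {vals}\n")
    return path
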