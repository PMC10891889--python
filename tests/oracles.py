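"""Independent brute-force oracles used to validate the package's optimized
implementations.  Everything here favours directness over speed and shares
no code with the implementations under test."""

import itertools

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
STOPS = {"TAA", "TAG", "TGA"}

IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
         "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT",
         "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT"}


def revcomp(s):
    return "".join(COMP.get(c, "N") for c in reversed(s))


# --------------------------------------------------------------------------
# circular six-frame ORF enumeration

def brute_orfs(seq, min_aa=50, circular=True):
    """Every (start, end, strand, length_aa), 1-based inclusive plus-strand
    span coordinates, from exhaustive position-by-position scanning with the
    longest-variant (most-upstream ATG) rule."""
    L = len(seq)
    results = set()
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        ss = s * 3
        # candidate: ATG at p, walk to first in-frame stop; group candidates
        # by their stop so only the most-upstream ATG variant survives
        by_stop = {}
        for p in range(L if circular else L - 2):
            if ss[p:p + 3] != "ATG":
                continue
            stop_at = None
            walker = p
            while walker + 3 - p <= L:
                cod = ss[walker:walker + 3]
                if len(cod) < 3 or (not circular and walker + 3 > L):
                    break
                if cod in STOPS:
                    stop_at = walker
                    break
                walker += 3
            if stop_at is None:
                continue
            nt = stop_at + 3 - p
            if nt > L:
                continue
            key = (stop_at % L if circular else stop_at)
            prev = by_stop.get(key)
            if prev is None or nt > prev[1]:
                by_stop[key] = (p, nt)
        for stop_key, (p, nt) in by_stop.items():
            aa = nt // 3 - 1
            if aa < min_aa:
                continue
            a0, e0 = p % L, (p + nt - 1) % L
            if strand == "+":
                start0, end0 = a0, e0
            else:
                start0, end0 = (L - 1 - e0) % L, (L - 1 - a0) % L
            results.add((start0 + 1, end0 + 1, strand, aa))
    return results


# --------------------------------------------------------------------------
# IUPAC motif scanning by concrete expansion

def expand_motif(motif):
    return {"".join(p) for p in itertools.product(*(IUPAC[c] for c in motif))}


def brute_scan(window, motif):
    concrete = expand_motif(motif)
    m = len(motif)
    w = len(window)
    return [i - w for i in range(w - m + 1) if window[i:i + m] in concrete]


# --------------------------------------------------------------------------
# palindrome enumeration

def brute_palindromes(seq, min_arm=10, max_gap=8, max_mismatch=3):
    """All maximal imperfect inverted repeats, as (start0, end0, arm,
    mismatches, gap) with 0-based inclusive outer coordinates; per
    (center, gap) the largest arm ending on a matching pair; deduplicated on
    outer span keeping the largest arm / fewest mismatches."""
    n = len(seq)

    def mm(center, gap, arm):
        left = seq[center - arm:center]
        right = seq[center + gap:center + gap + arm]
        return sum(1 for x, y in zip(left, revcomp(right)) if
                   x != y or x not in COMP)

    def outer_match(center, gap, arm):
        a, b = seq[center - arm], seq[center + gap + arm - 1]
        return a in COMP and COMP[a] == b

    found = {}
    for gap in range(max_gap + 1):
        for center in range(1, n):
            best = None
            for arm in range(1, min(center, n - center - gap) + 1):
                if mm(center, gap, arm) <= max_mismatch and \
                        outer_match(center, gap, arm):
                    best = arm
            if best is not None and best >= min_arm:
                key = (center - best, center + gap + best - 1)
                cand = (best, mm(center, gap, best), gap)
                prev = found.get(key)
                if prev is None or (cand[0], -cand[1]) > (prev[0], -prev[1]):
                    found[key] = cand
    return {(s, e, arm, m, g) for (s, e), (arm, m, g) in found.items()}


# --------------------------------------------------------------------------
# alignment oracles

def gotoh_score(a, b, match=5.0, mismatch=-4.0, gap_open=-10.0,
                gap_extend=-0.5):
    """Plain-loop affine global alignment score; gap of length L costs
    gap_open + (L-1)*gap_extend."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] in "ACGT") \
                else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, X[i][j - 1] + gap_open,
                          Y[i][j - 1] + gap_extend)
    return max(M[n][m], X[n][m], Y[n][m])


def enum_global_score(a, b, match=5.0, mismatch=-4.0, gap_open=-10.0,
                      gap_extend=-0.5):
    """Exhaustive recursive enumeration of all global alignments (tiny
    inputs only)."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def go(i, j, state):
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            s = match if (a[i] == b[j] and a[i] in "ACGT") else mismatch
            best = max(best, s + go(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if state == "X" else gap_open
            best = max(best, cost + go(i + 1, j, "X"))
        if j < len(b):
            cost = gap_extend if state == "Y" else gap_open
            best = max(best, cost + go(i, j + 1, "Y"))
        return best

    return go(0, 0, "M")


def local_blosum_score(p1, p2, gap_open=-11.0, gap_extend=-1.0):
    """Plain-loop Smith-Waterman with BLOSUM62; gap of length L costs
    gap_open + (L-1)*gap_extend."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    NEG = float("-inf")
    n, m = len(p1), len(p2)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = mat[p1[i - 1], p2[j - 1]]
            M[i][j] = max(0.0, M[i - 1][j - 1] + s, X[i - 1][j - 1] + s,
                          Y[i - 1][j - 1] + s)
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
            best = max(best, M[i][j])
    return best
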