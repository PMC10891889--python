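"""Affine-gap global alignment in linear space.

Implements Gotoh's three-state dynamic programme and a Myers-Miller
divide-and-conquer driver so that end-to-end DNA alignments (marker genes,
whole genomes) never need a quadratic traceback matrix.

Conventions
-----------
* Gap cost: a run of L gap characters scores ``gap_open + (L-1)*gap_extend``
  (the EMBOSS convention; ``gap_open``/``gap_extend`` are negative scores).
* A match requires both characters to be identical *and* unambiguous
  (A/C/G/T); N and other IUPAC ambiguity codes always score as mismatches.
* Tie-breaking in traceback: diagonal (match/mismatch) is preferred over
  gaps, and a gap in ``seq_a`` is preferred over a gap in ``seq_b``.

States: M = diagonal; Y = gap in seq_a (consumes b); X = gap in seq_b
(consumes a).
"""

from __future__ import annotations

import numpy as np

NEG_INF = float("-inf")

# start-boundary conditions for sub-alignments in the divide-and-conquer
START_FREE = 0      # alignment may start in any state
START_X_CONT = 1    # must start in X; first gapped residue costs gap_extend
START_X_OPEN = 2    # must start in X; normal gap charging

_ACGT = frozenset(b"ACGT")

# leaf size (in DP cells) below which the quadratic traceback DP is used
_LEAF_CELLS = 2048


def _subst(ca: int, cb: int, match: float, mismatch: float) -> float:
    return match if (ca == cb and ca in _ACGT) else mismatch


def _score_pass(a: bytes, b: bytes, match: float, mismatch: float,
                gap_open: float, gap_extend: float, start: int):
    """One linear-space forward pass.

    Returns ``(CC, DD)`` over j = 0..len(b): CC[j] is the best score of
    aligning all of ``a`` against ``b[:j]`` ending in any state, DD[j] the
    best ending in state X (gap in seq_b).
    """
    n, m = len(a), len(b)
    barr = np.frombuffer(b, dtype=np.uint8)
    bvalid = np.isin(barr, np.frombuffer(b"ACGT", dtype=np.uint8))
    jj = np.arange(m + 1, dtype=float)

    M = np.full(m + 1, NEG_INF)
    X = np.full(m + 1, NEG_INF)
    Y = np.full(m + 1, NEG_INF)
    if start == START_FREE:
        M[0] = 0.0
    else:
        X[0] = 0.0 if start == START_X_CONT else gap_open - gap_extend
    # row 0 horizontal gaps (start of alignment); reachable from M or X state 0
    base0 = max(M[0], X[0])
    if m > 0 and base0 > NEG_INF:
        Y[1:] = base0 + gap_open + (jj[1:] - 1) * gap_extend

    for i in range(1, n + 1):
        ca = a[i - 1]
        if ca in _ACGT:
            sub = np.where((barr == ca) & bvalid, match, mismatch)
        else:
            sub = np.full(m, mismatch)
        best_prev = np.maximum(np.maximum(M, X), Y)
        newX = np.maximum(np.maximum(M + gap_open, X + gap_extend), Y + gap_open)
        newM = np.full(m + 1, NEG_INF)
        if m > 0:
            newM[1:] = best_prev[:-1] + sub
        # horizontal pass: Y[j] = max_{k<j} max(newM,newX)[k] + open + (j-k-1)*ext
        base = np.maximum(newM, newX)
        with np.errstate(invalid="ignore"):
            c = base + gap_open - gap_extend * (jj + 1)
        acc = np.maximum.accumulate(c)
        newY = np.full(m + 1, NEG_INF)
        if m > 0:
            newY[1:] = gap_extend * jj[1:] + acc[:-1]
        M, X, Y = newM, newX, newY

    CC = np.maximum(np.maximum(M, X), Y)
    return CC, X.copy()


def _gotoh_full(a: bytes, b: bytes, match: float, mismatch: float,
                gap_open: float, gap_extend: float, start: int, end_x: bool):
    """Quadratic-space Gotoh with traceback for leaf subproblems."""
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    if start == START_FREE:
        M[0, 0] = 0.0
    else:
        X[0, 0] = 0.0 if start == START_X_CONT else gap_open - gap_extend
    for j in range(1, m + 1):
        cands = [M[0, j - 1] + gap_open, X[0, j - 1] + gap_open,
                 Y[0, j - 1] + gap_extend]
        Y[0, j] = max(cands)
    for i in range(1, n + 1):
        X[i, 0] = max(M[i - 1, 0] + gap_open, X[i - 1, 0] + gap_extend,
                      Y[i - 1, 0] + gap_open)
        ca = a[i - 1]
        for j in range(1, m + 1):
            s = _subst(ca, b[j - 1], match, mismatch)
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, X[i, j - 1] + gap_open,
                          Y[i, j - 1] + gap_extend)

    # traceback; tie order: M (diagonal) > Y (gap in a) > X (gap in b)
    if end_x:
        state, score = "X", X[n, m]
    else:
        score = max(M[n, m], Y[n, m], X[n, m])
        state = "M" if M[n, m] == score else ("Y" if Y[n, m] == score else "X")
    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if state == "M":
            s = _subst(a[i - 1], b[j - 1], match, mismatch)
            out_a.append(a[i - 1:i])
            out_b.append(b[j - 1:j])
            tgt = M[i, j] - s
            i, j = i - 1, j - 1
            state = ("M" if M[i, j] == tgt else
                     "Y" if Y[i, j] == tgt else "X")
        elif state == "Y":
            out_a.append(b"-")
            out_b.append(b[j - 1:j])
            v = Y[i, j]
            j -= 1
            if M[i, j] + gap_open == v:
                state = "M"
            elif Y[i, j] + gap_extend == v:
                state = "Y"
            else:
                state = "X"
        else:  # X
            out_a.append(a[i - 1:i])
            out_b.append(b"-")
            v = X[i, j]
            i -= 1
            if M[i, j] + gap_open == v:
                state = "M"
            elif X[i, j] + gap_extend == v:
                state = "X"
            else:
                state = "Y"
    out_a.reverse()
    out_b.reverse()
    return b"".join(out_a), b"".join(out_b), float(score)


def _mm(a: bytes, b: bytes, match, mismatch, gap_open, gap_extend,
        start: int, end_x: bool):
    n, m = len(a), len(b)
    if n * m <= _LEAF_CELLS or n <= 1 or m <= 1:
        return _gotoh_full(a, b, match, mismatch, gap_open, gap_extend,
                           start, end_x)
    mid = n // 2
    CCf, DDf = _score_pass(a[:mid], b, match, mismatch, gap_open, gap_extend,
                           start)
    # reverse pass on reversed suffixes; end-x constraint becomes a start
    # constraint with normal charging
    rstart = START_X_OPEN if end_x else START_FREE
    CCr_rev, DDr_rev = _score_pass(a[mid:][::-1], b[::-1], match, mismatch,
                                   gap_open, gap_extend, rstart)
    CCr, DDr = CCr_rev[::-1], DDr_rev[::-1]
    t1 = CCf + CCr
    t2 = DDf + DDr + (gap_extend - gap_open)
    j1 = int(np.argmax(t1))
    j2 = int(np.argmax(t2))
    if t1[j1] >= t2[j2]:
        j = j1
        la, lb, ls = _mm(a[:mid], b[:j], match, mismatch, gap_open, gap_extend,
                         start, False)
        ra, rb, rs = _mm(a[mid:], b[j:], match, mismatch, gap_open, gap_extend,
                         START_FREE, end_x)
    else:
        j = j2
        la, lb, ls = _mm(a[:mid], b[:j], match, mismatch, gap_open, gap_extend,
                         start, True)
        ra, rb, rs = _mm(a[mid:], b[j:], match, mismatch, gap_open, gap_extend,
                         START_X_CONT, end_x)
    return la + ra, lb + rb, ls + rs


def align_global(a: str, b: str, match: float = 5.0, mismatch: float = -4.0,
                 gap_open: float = -10.0, gap_extend: float = -0.5):
    """Optimal end-to-end affine-gap alignment in linear space.

    Returns ``(aligned_a, aligned_b, score)``.
    """
    if not a or not b:
        raise ValueError("cannot globally align an empty sequence")
    aa, bb, score = _mm(a.upper().encode(), b.upper().encode(), match,
                        mismatch, gap_open, gap_extend, START_FREE, False)
    return aa.decode(), bb.decode(), score


def score_global(a: str, b: str, match: float = 5.0, mismatch: float = -4.0,
                 gap_open: float = -10.0, gap_extend: float = -0.5) -> float:
    """Score-only linear-space global alignment (single forward pass)."""
    if not a or not b:
        raise ValueError("cannot globally align an empty sequence")
    CC, _ = _score_pass(a.upper().encode(), b.upper().encode(), match,
                        mismatch, gap_open, gap_extend, START_FREE)
    return float(CC[-1])


def alignment_identity(aligned_a: str, aligned_b: str) -> float:
    """Percent identical columns over the full alignment length."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences differ in length")
    if not aligned_a:
        return 0.0
    ident = sum(1 for x, y in zip(aligned_a, aligned_b)
                if x == y and x in "ACGT")
    return 100.0 * ident / len(aligned_a)
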