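"""De novo detection of homologous regions (hrs).

Baculovirus hrs are AT-rich loci of tandem ~112-bp repeat units, each unit
carrying an imperfect ~26-bp palindromic core near its centre; they act as
replication origins and early-promoter enhancers.  Detection here is
two-stage: (1) maximal tandem arrays are found from spaced k-mer match
distances and refined against the array consensus; (2) an array is promoted
to an hr locus iff its unit consensus contains an imperfect palindrome in
the central third of the unit.  AT-richness is annotated, never used as a
filter.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .genome import CircularGenome, reverse_complement, span_length

__all__ = ["RepeatUnit", "Palindrome", "HrLocus", "TandemArray",
           "find_tandem_repeats", "find_palindromes", "assemble_hrs",
           "hr_report"]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class RepeatUnit:
    """One tandem-repeat unit (1-based inclusive genome coordinates)."""

    start: int
    end: int
    sequence: str
    identity_to_consensus: float


@dataclass
class Palindrome:
    """An inverted repeat: ``center`` is the 1-based position of the first
    base after the left arm (within the searched sequence); ``span`` is
    ``2*arm_len + gap``."""

    center: int
    arm_len: int
    mismatches: int
    gap: int

    @property
    def span(self) -> int:
        return 2 * self.arm_len + self.gap

    @property
    def start(self) -> int:
        return self.center - self.arm_len

    @property
    def end(self) -> int:
        return self.center + self.gap + self.arm_len - 1


@dataclass
class TandemArray:
    """A candidate tandem-repeat array on a linear coordinate system."""

    start: int          # 1-based inclusive
    end: int
    period: int
    copy_number: float
    unit_starts: list = field(default_factory=list)  # 1-based starts of full units
    consensus: str = ""
    identities: list = field(default_factory=list)   # per full unit, percent

    @property
    def n_units(self) -> int:
        return len(self.unit_starts)

    @property
    def mean_identity(self) -> float:
        return sum(self.identities) / len(self.identities) if self.identities else 0.0


@dataclass
class HrLocus:
    """A homologous region: ordered repeat units with a palindromic core."""

    name: str
    start: int
    end: int
    units: list
    consensus: str
    palindrome: Palindrome
    at_percent: float


# ---------------------------------------------------------------------------
# tandem repeats

def _consensus(units):
    """Majority-vote per column; ties resolved toward the first unit."""
    cols = []
    for j in range(len(units[0])):
        counts = Counter(u[j] for u in units)
        top = max(counts.values())
        winners = [b for b, c in counts.items() if c == top]
        first = units[0][j]
        cols.append(first if first in winners else sorted(winners)[0])
    return "".join(cols)


def _identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return 100.0 * sum(1 for x, y in zip(a, b) if x == y and x in "ACGT") / n


def find_tandem_repeats(seq: str, min_period: int = 50, max_period: int = 250,
                        min_copies: float = 2.0, min_identity: float = 70.0,
                        k: int = 12):
    """Detect maximal tandem arrays in ``seq``.

    The period is estimated from the modal distance between consecutive
    occurrences of shared k-mers; array boundaries are refined on the
    periodic self-match profile (``seq[i] == seq[i+p]``) and units are cut at
    the estimated period and compared to their majority consensus.
    Overlapping candidates are merged keeping the higher copy-number call.
    Returns a list of :class:`TandemArray` (1-based coordinates in ``seq``).
    """
    seq = seq.upper()
    n = len(seq)
    if n < 2 * min_period:
        return []
    occ = defaultdict(list)
    for i in range(n - k + 1):
        occ[seq[i:i + k]].append(i)
    matches = []  # (pos, dist) of consecutive same-k-mer occurrences
    for kmer, positions in occ.items():
        if "N" in kmer or len(positions) < 2:
            continue
        for a, b in zip(positions, positions[1:]):
            d = b - a
            if min_period <= d <= max_period:
                matches.append((a, d))
    matches.sort()

    # cluster matches into candidate arrays with a consistent distance
    clusters = []
    cur = []
    for pos, d in matches:
        if cur and abs(d - cur[-1][1]) <= 8 and pos - cur[-1][0] <= cur[-1][1]:
            cur.append((pos, d))
        else:
            if len(cur) >= 3:
                clusters.append(cur)
            cur = [(pos, d)]
    if len(cur) >= 3:
        clusters.append(cur)

    arrays = []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    for cluster in clusters:
        dists = [d for _, d in cluster]
        p = Counter(dists).most_common(1)[0][0]
        if not (min_period <= p <= max_period):
            continue
        # refine boundaries on the periodic self-match profile
        # mvec[i] <=> seq[i] == seq[i+p]; array [S, E) has support [S, E-p)
        if n - p <= 0:
            continue
        mvec = arr[:-p] == arr[p:]
        W = 12  # windowed walk: tolerant of unit divergence, stops on background
        ms = cluster[0][0]
        me = min(cluster[-1][0], len(mvec) - 1)
        s = ms
        while s - W >= 0 and mvec[s - W:s].mean() >= 0.5:
            s -= W
        while s > 0 and mvec[s - 1]:
            s -= 1
        while s < ms and not mvec[s]:
            s += 1
        e = me
        while e + W + 1 < len(mvec) and mvec[e + 1:e + W + 1].mean() >= 0.5:
            e += W
        while e + 1 < len(mvec) and mvec[e + 1]:
            e += 1
        while e > s and not mvec[e]:
            e -= 1
        start0, end0 = s, min(e + 1 + p, n)  # [start0, end0) covers the array
        n_full = int(round((end0 - start0) / p))
        if n_full < 2:
            continue
        end0 = min(start0 + n_full * p, n)
        n_full = (end0 - start0) // p
        if n_full < 2:
            continue
        units = [seq[start0 + i * p: start0 + (i + 1) * p] for i in range(n_full)]
        cons = _consensus(units)
        idents = [_identity(u, cons) for u in units]
        # trim low-identity edge units
        while idents and idents[0] < min_identity:
            units, idents = units[1:], idents[1:]
            start0 += p
        while idents and idents[-1] < min_identity:
            units, idents = units[:-1], idents[:-1]
        if len(units) < 2:
            continue
        cons = _consensus(units)
        idents = [_identity(u, cons) for u in units]
        end0 = start0 + len(units) * p
        copy_number = round((end0 - start0) / p, 2)
        if copy_number < min_copies or (sum(idents) / len(idents)) < min_identity:
            continue
        arrays.append(TandemArray(
            start=start0 + 1, end=end0, period=p, copy_number=copy_number,
            unit_starts=[start0 + 1 + i * p for i in range(len(units))],
            consensus=cons, identities=idents))

    # merge overlapping candidates, keeping the higher copy-number call
    arrays.sort(key=lambda a: (-a.copy_number, -a.mean_identity, a.start))
    kept = []
    for a in arrays:
        if all(min(a.end, b.end) - max(a.start, b.start) < 0 for b in kept):
            kept.append(a)
    kept.sort(key=lambda a: a.start)
    return kept


# ---------------------------------------------------------------------------
# palindromes

def find_palindromes(seq: str, min_arm: int = 10, max_gap: int = 8,
                     max_mismatch: int = 3):
    """Maximal imperfect inverted repeats.

    For every centre and loop size (0..``max_gap``) the arms are extended as
    far as possible while the left arm and the reverse complement of the
    right arm differ at <= ``max_mismatch`` positions; the reported arm ends
    on a matching pair.  Results are sorted by span descending; palindromes
    sharing identical outer coordinates keep only the best (longest-arm,
    fewest-mismatch) representative.
    """
    seq = seq.upper()
    n = len(seq)
    found = {}
    for gap in range(0, max_gap + 1):
        for center in range(1, n):  # 0-based index of first base after left arm
            left = center - 1
            right = center + gap
            arm = 0
            mism = 0
            best_arm = 0
            best_mism = 0
            while left >= 0 and right < n:
                a, b = seq[left], seq[right]
                pair_match = a in _COMP and _COMP[a] == b
                if not pair_match:
                    mism += 1
                    if mism > max_mismatch:
                        break
                arm += 1
                if pair_match:
                    best_arm, best_mism = arm, mism
                left -= 1
                right += 1
            if best_arm >= min_arm:
                start = center - best_arm  # 0-based
                end = center + gap + best_arm - 1
                key = (start, end)
                cand = Palindrome(center=center + 1, arm_len=best_arm,
                                  mismatches=best_mism, gap=gap)
                prev = found.get(key)
                if prev is None or (cand.arm_len, -cand.mismatches) > \
                        (prev.arm_len, -prev.mismatches):
                    found[key] = cand
    out = list(found.values())
    out.sort(key=lambda p: (-p.span, p.start, p.mismatches))
    return out


# ---------------------------------------------------------------------------
# hr assembly

def _at_percent(s: str) -> float:
    at = s.count("A") + s.count("T")
    acgt = sum(s.count(b) for b in "ACGT")
    return 100.0 * at / acgt if acgt else 0.0


def assemble_hrs(arrays, genome: CircularGenome, min_arm: int = 10,
                 max_gap: int = 8, max_mismatch: int = 3):
    """Promote tandem arrays to hr loci.

    An array becomes an hr iff its unit consensus contains a palindrome
    (searched with the given parameters) whose centre lies in the central
    third of the unit.  Names hr1, hr2, ... are assigned in genome order
    from the origin.  AT content is recorded, not filtered on.
    """
    loci = []
    for arr in sorted(arrays, key=lambda a: a.start):
        pals = find_palindromes(arr.consensus, min_arm=min_arm,
                                max_gap=max_gap, max_mismatch=max_mismatch)
        p_len = len(arr.consensus)
        central = [p for p in pals
                   if p_len / 3 <= p.center - 0.5 <= 2 * p_len / 3]
        if not central:
            continue
        pal = central[0]  # largest span among central candidates
        units = [RepeatUnit(start=s, end=s + arr.period - 1,
                            sequence=genome.sequence[s - 1:s + arr.period - 1],
                            identity_to_consensus=i)
                 for s, i in zip(arr.unit_starts, arr.identities)]
        locus_seq = genome.sequence[arr.start - 1:arr.end]
        loci.append(HrLocus(name="", start=arr.start, end=arr.end,
                            units=units, consensus=arr.consensus,
                            palindrome=pal, at_percent=_at_percent(locus_seq)))
    loci.sort(key=lambda h: h.start)
    for i, h in enumerate(loci, 1):
        h.name = f"hr{i}"
    return loci


def hr_report(hrs, orfs, genome_length: int):
    """Flanking locus tags and a unit-alignment block for each hr.

    Flanks are the nearest annotated ORFs upstream and downstream on the
    circular map (by span boundaries).
    """
    rows = []
    for hr in hrs:
        up = down = None
        best_up = best_down = None
        for orf in orfs:
            # circular gap from ORF end to hr start
            gap_up = (hr.start - orf.end - 1) % genome_length
            gap_down = (orf.start - hr.end - 1) % genome_length
            if best_up is None or gap_up < best_up:
                best_up, up = gap_up, orf.locus_tag
            if best_down is None or gap_down < best_down:
                best_down, down = gap_down, orf.locus_tag
        lines = [f"{hr.name} {hr.start}..{hr.end} "
                 f"({len(hr.units)} units, AT {hr.at_percent:.1f}%)"]
        for u in hr.units:
            marks = "".join("|" if a == b else " "
                            for a, b in zip(u.sequence, hr.consensus))
            lines.append(f"  {u.start:>8} {u.sequence} {u.identity_to_consensus:5.1f}%")
            lines.append(f"           {marks}")
        lines.append(f" consensus {hr.consensus}")
        pal = hr.palindrome
        lines.append(f" palindrome span {pal.span} bp at consensus "
                     f"{pal.start}..{pal.end} ({pal.mismatches} mismatches)")
        rows.append({
            "name": hr.name, "start": hr.start, "end": hr.end,
            "n_units": len(hr.units), "period": len(hr.consensus),
            "at_percent": round(hr.at_percent, 1),
            "palindrome_span": pal.span,
            "palindrome_mismatches": pal.mismatches,
            "flank_upstream": up, "flank_downstream": down,
            "alignment": "\n".join(lines),
        })
    return rows
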