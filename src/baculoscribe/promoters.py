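"""Early/late promoter motif classification of ORF upstream regions.

Baculovirus early genes are transcribed by the host RNA polymerase II from a
TATA-box element (TATAW) with a CAKT mRNA start-site motif 25-35 nt
downstream, or from a TATA-like TAATWAA element; late genes initiate within
a DTAAG motif recognized by the viral RNA polymerase.  Each ORF's 180-nt
upstream window (on its coding strand) is screened for these motifs and
classified early / late / both / none.

Position convention: offsets are signed, with -1 the base immediately 5' of
the A of the initiation codon; a motif's position is the offset of its first
base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .genome import CircularGenome, extract_subsequence, span_length

logger = logging.getLogger(__name__)

__all__ = ["PromoterCall", "IUPAC_SETS", "upstream_window", "scan_motif",
           "classify_promoter", "promoter_summary",
           "EARLY_TATA", "EARLY_CAKT", "TATA_LIKE", "LATE_MOTIF"]

EARLY_TATA = "TATAW"
EARLY_CAKT = "CAKT"
TATA_LIKE = "TAATWAA"
LATE_MOTIF = "DTAAG"

MIN_SPACING = 25   # TATAW start -> CAKT start, inclusive bounds
MAX_SPACING = 35

# IUPAC degenerate nucleotide codes; N in the *window* never matches because
# window characters are compared against these unambiguous sets.
IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


class PatternError(ValueError):
    """Motif contains a letter outside the IUPAC alphabet."""


@dataclass
class PromoterCall:
    """Promoter classification of one ORF's upstream window."""

    locus_tag: str
    classification: str                      # early | late | both | none
    early_hits: list = field(default_factory=list)   # (tata_pos, cakt_pos, spacing)
    tata_like_hits: list = field(default_factory=list)
    late_hits: list = field(default_factory=list)


def upstream_window(genome: CircularGenome, orf, window: int = 180) -> str:
    """The upstream region of an ORF on its coding strand, 5'->3'.

    On a circular genome the window wraps but is capped at
    ``genome length - ORF length`` so it can never run through the ORF
    itself; on a linear genome it is truncated at the sequence edge.
    """
    L = genome.length
    orf_len = span_length(orf.start, orf.end, L)
    if genome.is_circular:
        w = min(window, L - orf_len)
        if w <= 0:
            return ""
        if orf.strand == "+":
            end = (orf.start - 2) % L + 1
            start = (orf.start - 1 - w) % L + 1
            return extract_subsequence(genome, start, end, "+")
        start = orf.end % L + 1
        end = (orf.end + w - 1) % L + 1
        return extract_subsequence(genome, start, end, "-")
    if orf.strand == "+":
        start = max(1, orf.start - window)
        if start > orf.start - 1:
            return ""
        if orf.start - start < window:
            logger.warning("%s: upstream window truncated to %d nt",
                           orf.locus_tag, orf.start - start)
        return extract_subsequence(genome, start, orf.start - 1, "+")
    end = min(L, orf.end + window)
    if end < orf.end + 1:
        return ""
    if end - orf.end < window:
        logger.warning("%s: upstream window truncated to %d nt",
                       orf.locus_tag, end - orf.end)
    return extract_subsequence(genome, orf.end + 1, end, "-")


def scan_motif(window: str, motif: str):
    """All (possibly overlapping) match offsets of an IUPAC motif.

    Offsets are signed: the last window base is -1.  Returns an empty list
    when the window is shorter than the motif.
    """
    motif = motif.upper()
    try:
        sets = [IUPAC_SETS[c] for c in motif]
    except KeyError as exc:
        raise PatternError(f"invalid IUPAC letter {exc.args[0]!r} in motif") from exc
    window = window.upper()
    w, m = len(window), len(motif)
    hits = []
    for i in range(w - m + 1):
        if all(window[i + j] in sets[j] for j in range(m)):
            hits.append(i - w)
    return hits


def classify_promoter(window: str, locus_tag: str = "") -> PromoterCall:
    """Classify one upstream window.

    early  <=> a TATAW hit with a CAKT hit 25-35 nt downstream (start to
    start, bounds inclusive), or a TAATWAA hit; late <=> a DTAAG hit;
    both/none accordingly.
    """
    tata = scan_motif(window, EARLY_TATA)
    cakt = scan_motif(window, EARLY_CAKT)
    tata_like = scan_motif(window, TATA_LIKE)
    late = scan_motif(window, LATE_MOTIF)
    early_hits = [(t, c, c - t) for t in tata for c in cakt
                  if MIN_SPACING <= c - t <= MAX_SPACING]
    has_early = bool(early_hits or tata_like)
    has_late = bool(late)
    if has_early and has_late:
        cls = "both"
    elif has_early:
        cls = "early"
    elif has_late:
        cls = "late"
    else:
        cls = "none"
    return PromoterCall(locus_tag=locus_tag, classification=cls,
                        early_hits=early_hits, tata_like_hits=tata_like,
                        late_hits=late)


def promoter_summary(calls) -> dict:
    """Census of promoter classes with motif-geometry averages.

    ``mean_tata_cakt_spacing`` averages the TATA->CAKT spacing over every
    early (TATAW+CAKT) hit; ``mean_late_offset`` averages one DTAAG offset
    per ORF whose window contains the late element (classes late and both),
    represented by the hit closest to the start codon.  Means are ``None``
    when no qualifying hit exists.
    """
    if not calls:
        raise ValueError("promoter_summary requires at least one call")
    counts = {"early": 0, "late": 0, "both": 0, "none": 0}
    spacings = []
    late_offsets = []
    for call in calls:
        counts[call.classification] += 1
        spacings.extend(sp for _, _, sp in call.early_hits)
        if call.late_hits:
            late_offsets.append(max(call.late_hits))
    return {
        "counts": counts,
        "n": len(calls),
        "mean_tata_cakt_spacing":
            (sum(spacings) / len(spacings)) if spacings else None,
        "mean_late_offset":
            (sum(late_offsets) / len(late_offsets)) if late_offsets else None,
    }
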