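"""ORF prediction on circular genomes and headline genome statistics.

Annotation conventions follow common baculovirus practice: ORFs encode at
least 50 amino acids, run from the most-upstream ATG to the first in-frame
stop, may span the origin of the circular map, and when two ORFs overlap by
more than 75 bp only the larger is kept unless the smaller is a conserved
baculovirus homolog.  ORFs lying entirely inside homologous regions (hrs)
are left unannotated because those loci are recombinationally unstable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .genome import (CircularGenome, FeatureRecord, extract_subsequence,
                     reverse_complement, span_length, span_intervals,
                     circular_overlap)

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")

__all__ = ["OrfFeature", "GenomeStats", "find_orfs", "resolve_overlaps",
           "mask_hr_orfs", "genome_stats", "classify_orfs",
           "assign_locus_tags", "orfs_to_features"]


@dataclass
class OrfFeature:
    """A predicted protein-coding feature.

    ``start``/``end`` are the plus-strand span boundaries (1-based inclusive,
    ``end < start`` for origin-spanning features).  For a minus-strand ORF the
    initiation codon sits at ``end``.  ``length_aa`` excludes the stop codon;
    the nucleotide span is ``3 * (length_aa + 1)``.  ``frame`` is the frame
    (0-2) of the span's first plus-strand base.
    """

    locus_tag: str
    start: int
    end: int
    strand: str
    length_aa: int
    frame: int
    translation: str
    annotation_class: str = "unique"   # core | conserved | common | unique
    is_homolog_of: str | None = None

    def span(self):
        return (self.start, self.end)

    def nt_length(self, genome_length: int) -> int:
        return span_length(self.start, self.end, genome_length)


@dataclass
class GenomeStats:
    length_bp: int
    gc_percent: float
    orf_count: int
    forward_count: int
    reverse_count: int
    coding_fraction_percent: float

    def as_dict(self) -> dict:
        return {
            "length_bp": self.length_bp,
            "gc_percent": round(self.gc_percent, 2),
            "orf_count": self.orf_count,
            "forward_count": self.forward_count,
            "reverse_count": self.reverse_count,
            "coding_fraction_percent": round(self.coding_fraction_percent, 2),
        }


def _scan_strand(seq: str, L: int, circular: bool, min_aa: int,
                 start_rule: str):
    """Find (start0, stop_end0) candidate ORFs on one strand of a linearized
    sequence.  ``seq`` is the doubled sequence for circular genomes.
    Coordinates are 0-based on ``seq``; the caller maps them back mod L.
    """
    out = []
    n = len(seq)
    min_nt = 3 * (min_aa + 1)
    for f in range(3):
        stops = [p for p in range(f, n - 2, 3) if seq[p:p + 3] in STOP_CODONS]
        segments = []
        if circular:
            # skip the leading segment (its upstream context wraps before the
            # window); every circular segment reappears bounded by two stops
            segments = [(stops[k] + 3, stops[k + 1])
                        for k in range(len(stops) - 1)]
        else:
            prev = f
            for s in stops:
                segments.append((prev, s))
                prev = s + 3
        for seg_start, stop_pos in segments:
            atgs = [p for p in range(seg_start, stop_pos, 3)
                    if seq[p:p + 3] == "ATG"]
            if not atgs:
                continue
            if start_rule == "longest":
                cands = atgs[:1]
            else:  # shortest variant still satisfying the length minimum
                ok = [p for p in atgs if stop_pos + 3 - p >= min_nt]
                cands = ok[-1:]
            for a in cands:
                nt = stop_pos + 3 - a
                if nt < min_nt:
                    continue
                if circular and nt > L:
                    continue
                out.append((a, stop_pos + 3))
    return out


def find_orfs(genome: CircularGenome, min_aa: int = 50,
              start_rule: str = "longest"):
    """Six-frame ORF scan, circular-aware.

    Each ORF runs from an ATG to the first in-frame stop; with the default
    ``start_rule='longest'`` the most-upstream ATG of each stop-bounded
    segment is reported.  Origin-spanning ORFs are reported once.
    """
    if start_rule not in ("longest", "shortest"):
        raise ValueError(f"unknown start_rule {start_rule!r}")
    L = genome.length
    if L < 3 * (min_aa + 1):
        logger.warning("genome of %d bp is shorter than the %d-aa ORF minimum",
                       L, min_aa)
        return []
    circular = genome.is_circular
    # tripled sequence: guarantees that for every circular ORF some linear
    # copy shows both its bounding upstream stop and its own stop codon
    scan_plus = genome.sequence * 3 if circular else genome.sequence
    rc = reverse_complement(genome.sequence)
    scan_minus = rc * 3 if circular else rc

    orfs = []
    seen = set()
    for strand, scan in (("+", scan_plus), ("-", scan_minus)):
        for a, e in _scan_strand(scan, L, circular, min_aa, start_rule):
            am, em = a % L, (e - 1) % L  # inclusive 0-based, own-strand coords
            if strand == "+":
                start0, end0 = am, em
            else:
                start0, end0 = (L - 1 - em) % L, (L - 1 - am) % L
            key = (start0, end0, strand)
            if key in seen:
                continue
            seen.add(key)
            start, end = start0 + 1, end0 + 1
            nt = e - a
            cds = extract_subsequence(genome, start, end, strand)
            prot = str(Seq(cds[:-3]).translate())
            orfs.append(OrfFeature(
                locus_tag="", start=start, end=end, strand=strand,
                length_aa=nt // 3 - 1, frame=start0 % 3, translation=prot))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def assign_locus_tags(orfs, prefix: str = "ORF"):
    """Name ORFs ``<prefix>_NNN`` in ascending start order from the origin."""
    for i, orf in enumerate(sorted(orfs, key=lambda o: (o.start, o.end)), 1):
        orf.locus_tag = f"{prefix}_{i:03d}"
    return sorted(orfs, key=lambda o: (o.start, o.end, o.strand))


def resolve_overlaps(orfs, genome_length: int, homolog_hits=None,
                     max_overlap_bp: int = 75):
    """Drop the smaller ORF of every pair overlapping by more than
    ``max_overlap_bp`` (circular, plus-strand projected) unless the smaller
    ORF is flagged as a conserved homolog.  Stable: input order preserved."""
    homolog_hits = homolog_hits or {}
    n = len(orfs)
    removed = set()
    for i in range(n):
        for j in range(i + 1, n):
            a, b = orfs[i], orfs[j]
            ov = circular_overlap(a.span(), b.span(), genome_length)
            if ov <= max_overlap_bp:
                continue
            la, lb = a.nt_length(genome_length), b.nt_length(genome_length)
            if la > lb:
                big, small = i, j
            elif lb > la:
                big, small = j, i
            else:
                # tie: keep the plus-strand ORF, then the lower start
                order = sorted([i, j], key=lambda k: (orfs[k].strand != "+",
                                                      orfs[k].start))
                big, small = order[0], order[1]
            if not homolog_hits.get(orfs[small].locus_tag, False):
                removed.add(small)
    return [o for k, o in enumerate(orfs) if k not in removed]


def _positions(start: int, end: int, L: int):
    for s, e in span_intervals(start, end, L):
        yield from range(s, e + 1)


def mask_hr_orfs(orfs, hrs, genome_length: int):
    """Remove ORFs lying entirely within an hr locus (partial overlaps kept)."""
    if not hrs:
        return list(orfs)
    hr_pos = set()
    for hr in hrs:
        hr_pos.update(_positions(hr.start, hr.end, genome_length))
    kept = []
    for orf in orfs:
        inside = all(p in hr_pos
                     for p in _positions(orf.start, orf.end, genome_length))
        if not inside:
            kept.append(orf)
    return kept


def genome_stats(genome: CircularGenome, orfs) -> GenomeStats:
    """G+C percent (ambiguous bases excluded) plus ORF census and coding
    fraction over the union of ORF spans projected to the plus strand."""
    seq = genome.sequence
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    gc_percent = 100.0 * gc / (gc + at) if gc + at else 0.0
    L = genome.length
    covered = np.zeros(L, dtype=bool)
    for orf in orfs:
        for s, e in span_intervals(orf.start, orf.end, L):
            covered[s - 1:e] = True
    fwd = sum(1 for o in orfs if o.strand == "+")
    return GenomeStats(
        length_bp=L, gc_percent=gc_percent, orf_count=len(orfs),
        forward_count=fwd, reverse_count=len(orfs) - fwd,
        coding_fraction_percent=float(100.0 * covered.mean()) if L else 0.0)


def classify_orfs(orfs, reference_sets, min_score: float = 100.0,
                  min_identity: float = 25.0):
    """Assign each ORF the highest-priority annotation class (core >
    conserved > common > unique) for which a reciprocal-best-hit match to the
    named reference protein collection exists."""
    from .comparative import reciprocal_best_hits

    priority = ["core", "conserved", "common"]
    if not reference_sets or not any(reference_sets.get(k) for k in priority):
        warnings.warn("empty reference sets: all ORFs classified as unique")
        for orf in orfs:
            orf.annotation_class = "unique"
            orf.is_homolog_of = None
        return orfs
    proteome = {o.locus_tag: o.translation for o in orfs}
    assigned = {}
    for cls in priority:
        refs = reference_sets.get(cls) or {}
        if not refs:
            continue
        pairs = reciprocal_best_hits(proteome, refs, min_score=min_score,
                                     min_identity=min_identity)
        for p in pairs:
            if p.locus_a not in assigned:
                assigned[p.locus_a] = (cls, p.locus_b)
    for orf in orfs:
        cls, ref = assigned.get(orf.locus_tag, ("unique", None))
        orf.annotation_class = cls
        orf.is_homolog_of = ref
    return orfs


def orfs_to_features(orfs):
    """Convert OrfFeature objects to generic FeatureRecords for writing."""
    feats = []
    for o in orfs:
        quals = {"translation": o.translation,
                 "annotation_class": o.annotation_class}
        if o.is_homolog_of:
            quals["homolog_of"] = o.is_homolog_of
        feats.append(FeatureRecord(locus_tag=o.locus_tag, start=o.start,
                                   end=o.end, strand=o.strand, kind="CDS",
                                   qualifiers=quals))
    return feats
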