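"""Circular-genome containers, I/O and coordinate arithmetic.

Baculovirus genomes are single circular dsDNA molecules; every downstream
stage (ORF calling, promoter scanning, repeat detection) needs wrap-aware
coordinate arithmetic.  Coordinates are 1-based inclusive throughout, the
GenBank convention; an origin-spanning feature on a circular genome is
encoded as ``end < start`` internally and written as ``join(start..L,1..end)``
in GenBank output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqFeature import SeqFeature, SimpleLocation, CompoundLocation

__all__ = [
    "CircularGenome",
    "FeatureRecord",
    "GenomeError",
    "FormatError",
    "EmptyInputError",
    "AlphabetError",
    "TopologyError",
    "ValidationError",
    "reverse_complement",
    "read_genome",
    "read_features",
    "extract_subsequence",
    "rotate_to_origin",
    "write_annotation",
    "span_length",
    "span_intervals",
    "circular_overlap",
]

# IUPAC nucleotide alphabet accepted on input; analysis code treats anything
# outside {A,C,G,T} as ambiguous (never matching a motif or codon).
IUPAC_DNA = set("ACGTNRYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


class GenomeError(Exception):
    """Base class for genome-handling errors."""


class FormatError(GenomeError):
    """File could not be parsed in the requested format."""


class EmptyInputError(GenomeError):
    """Input file contained no sequence records."""


class AlphabetError(GenomeError):
    """Sequence contains characters outside the IUPAC DNA alphabet."""


class TopologyError(GenomeError):
    """A circular operation was requested on a linear genome."""


class ValidationError(GenomeError):
    """A feature is inconsistent with its genome."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CircularGenome:
    """A (usually circular) DNA genome.

    Parameters
    ----------
    id : str
        Record identifier.
    sequence : str
        Upper-case DNA over the IUPAC alphabet.
    topology : {"circular", "linear"}
    origin_note : str
        Free-text note recording which feature defines position 1
        (for baculoviruses, conventionally the polyhedrin start codon).
    """

    id: str
    sequence: str
    topology: str = "circular"
    origin_note: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValidationError("genome sequence must be non-empty")
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise AlphabetError(f"non-DNA characters in sequence: {sorted(bad)!r}")
        if self.topology not in ("circular", "linear"):
            raise ValidationError(f"unknown topology {self.topology!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"


@dataclass
class FeatureRecord:
    """A located feature on a genome (1-based inclusive coordinates).

    ``end < start`` encodes an origin-spanning feature and is only valid on a
    circular genome.
    """

    locus_tag: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "other"  # CDS | hr | repeat | other
    qualifiers: dict = field(default_factory=dict)

    def validate(self, genome: CircularGenome) -> None:
        L = genome.length
        if not (1 <= self.start <= L and 1 <= self.end <= L):
            raise ValidationError(
                f"{self.locus_tag}: coordinates {self.start}..{self.end} "
                f"outside [1, {L}]")
        if self.end < self.start and not genome.is_circular:
            raise TopologyError(
                f"{self.locus_tag}: origin-spanning feature on linear genome")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.locus_tag}: bad strand {self.strand!r}")


def span_length(start: int, end: int, genome_length: int) -> int:
    """Length in bp of the 1-based inclusive span ``start..end`` (wrapping)."""
    if end >= start:
        return end - start + 1
    return genome_length - start + 1 + end


def span_intervals(start: int, end: int, genome_length: int):
    """Decompose a (possibly wrapping) span into 1-2 linear intervals."""
    if end >= start:
        return [(start, end)]
    return [(start, genome_length), (1, end)]


def circular_overlap(span_a, span_b, genome_length: int) -> int:
    """Overlap in bp between two circular spans given as (start, end) tuples."""
    total = 0
    for a1, a2 in span_intervals(*span_a, genome_length):
        for b1, b2 in span_intervals(*span_b, genome_length):
            lo, hi = max(a1, b1), min(a2, b2)
            if hi >= lo:
                total += hi - lo + 1
    return total


def extract_subsequence(genome: CircularGenome, start: int, end: int,
                        strand: str = "+") -> str:
    """Return the 1-based inclusive span; wraps through the origin when
    ``end < start`` on a circular genome.  Strand ``-`` returns the reverse
    complement of the plus-strand span (i.e. the coding-strand sequence of a
    minus-strand feature, 5'->3')."""
    L = genome.length
    if not (1 <= start <= L and 1 <= end <= L):
        raise ValidationError(f"coordinates {start}..{end} outside [1, {L}]")
    if end >= start:
        sub = genome.sequence[start - 1:end]
    else:
        if not genome.is_circular:
            raise TopologyError("wraparound extraction on a linear genome")
        sub = genome.sequence[start - 1:] + genome.sequence[:end]
    if strand == "-":
        sub = reverse_complement(sub)
    elif strand != "+":
        raise ValidationError(f"bad strand {strand!r}")
    return sub


def rotate_to_origin(genome: CircularGenome, position: int) -> CircularGenome:
    """Return the genome re-linearized so that ``position`` becomes base 1.

    Used to apply the polyhedrin-origin convention in which the polh start
    codon defines the top of the physical map.
    """
    if not genome.is_circular:
        raise TopologyError("cannot rotate a linear genome")
    L = genome.length
    if not (1 <= position <= L):
        raise ValidationError(f"rotation position {position} outside [1, {L}]")
    seq = genome.sequence[position - 1:] + genome.sequence[:position - 1]
    return CircularGenome(id=genome.id, sequence=seq, topology=genome.topology,
                          origin_note=f"rotated so former position {position} is base 1")


def rotate_feature(feature: FeatureRecord, position: int,
                   genome_length: int) -> FeatureRecord:
    """Shift a feature's coordinates to match rotate_to_origin(genome, position)."""
    def shift(p):
        return (p - position) % genome_length + 1

    return FeatureRecord(locus_tag=feature.locus_tag, start=shift(feature.start),
                         end=shift(feature.end), strand=feature.strand,
                         kind=feature.kind, qualifiers=dict(feature.qualifiers))


# ---------------------------------------------------------------------------
# reading

_FASTA_EXT = {".fa", ".fasta", ".fna"}
_GENBANK_EXT = {".gb", ".gbk", ".gbff", ".genbank"}


def _sniff_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in _FASTA_EXT:
        return "fasta"
    if ext in _GENBANK_EXT:
        return "genbank"
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fasta" if line.startswith(">") else "genbank"
    raise EmptyInputError(f"{path}: empty file")


def _feature_from_seqfeature(feat: SeqFeature, genome_length: int, idx: int) -> FeatureRecord:
    qualifiers = {k: (v[0] if isinstance(v, list) and v else v)
                  for k, v in feat.qualifiers.items()}
    tag = qualifiers.get("locus_tag") or qualifiers.get("ID") or f"feat_{idx:03d}"
    strand = "-" if (feat.location.strand or 1) < 0 else "+"
    parts = sorted(feat.location.parts, key=lambda p: int(p.start))
    if len(parts) == 2 and int(parts[1].end) == genome_length and int(parts[0].start) == 0:
        # join(a..L, 1..b): origin-spanning
        start = int(parts[1].start) + 1
        end = int(parts[0].end)
    else:
        start = int(feat.location.start) + 1
        end = int(feat.location.end)
    kind = {"CDS": "CDS", "repeat_region": "repeat"}.get(feat.type, "other")
    if qualifiers.get("rpt_family") == "hr" or qualifiers.get("note", "").startswith("hr"):
        kind = "hr" if kind == "repeat" else kind
    return FeatureRecord(locus_tag=str(tag), start=start, end=end, strand=strand,
                         kind=kind, qualifiers=qualifiers)


def read_genome(path: str, format: str = "auto", topology: str = "circular"):
    """Read the first sequence record of a FASTA or GenBank file.

    Returns ``(CircularGenome, list[FeatureRecord])``.  FASTA yields an empty
    feature list; GenBank CDS and repeat_region features are converted.  The
    topology is taken from the GenBank LOCUS line when present, otherwise from
    the ``topology`` argument.
    """
    if format == "auto":
        format = _sniff_format(path)
    if format not in ("fasta", "genbank"):
        raise FormatError(f"unknown format {format!r}")
    try:
        records = list(SeqIO.parse(path, format))
    except Exception as exc:  # Biopython raises assorted ValueError subclasses
        raise FormatError(f"{path}: cannot parse as {format}: {exc}") from exc
    if not records:
        raise EmptyInputError(f"{path}: no {format} records found")
    rec = records[0]
    seq = str(rec.seq).upper()
    if format == "genbank":
        topology = rec.annotations.get("topology", topology)
    genome = CircularGenome(id=rec.id, sequence=seq, topology=topology,
                            origin_note=str(rec.description or ""))
    features = []
    if format == "genbank":
        for i, feat in enumerate(rec.features):
            if feat.type in ("CDS", "repeat_region"):
                features.append(_feature_from_seqfeature(feat, genome.length, i))
    return genome, features


def read_features(path: str, format: str = "auto", genome_length: int | None = None):
    """Read a feature table written by :func:`write_annotation` (gff3 or tsv)."""
    if format == "auto":
        ext = os.path.splitext(path)[1].lower()
        format = {"gff3": "gff3", ".gff3": "gff3", ".gff": "gff3",
                  ".tsv": "tsv"}.get(ext, "tsv")
    feats = []
    if format == "gff3":
        import gffutils
        from gffutils.exceptions import EmptyInputError as GffEmpty

        try:
            db = gffutils.create_db(path, dbfn=":memory:", force=True,
                                    keep_order=True,
                                    merge_strategy="create_unique")
        except GffEmpty:
            return []  # header-only file: no features
        for f in db.all_features():
            if f.featuretype == "region":
                continue
            start, end = f.start, f.end
            if genome_length and end > genome_length:
                end -= genome_length  # origin-spanning convention
            tag = f.attributes.get("ID", [f.id])[0]
            kind = {"CDS": "CDS", "repeat_region": "repeat",
                    "biological_region": "other"}.get(f.featuretype, f.featuretype)
            if kind == "repeat" and f.attributes.get("rpt_family", [""])[0] == "hr":
                kind = "hr"
            quals = {k: v[0] for k, v in f.attributes.items()
                     if k not in ("ID", "rpt_family")}
            feats.append(FeatureRecord(locus_tag=tag, start=start, end=end,
                                       strand=f.strand or "+", kind=kind,
                                       qualifiers=quals))
    elif format == "tsv":
        with open(path) as fh:
            header = None
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                if header is None:
                    header = line.split("\t")
                    continue
                row = dict(zip(header, line.split("\t")))
                feats.append(FeatureRecord(
                    locus_tag=row["locus_tag"], start=int(row["start"]),
                    end=int(row["end"]), strand=row["strand"], kind=row["kind"]))
    else:
        raise FormatError(f"unknown feature format {format!r}")
    return feats


# ---------------------------------------------------------------------------
# writing

def _seqfeature_from_feature(feat: FeatureRecord, genome: CircularGenome) -> SeqFeature:
    strand = -1 if feat.strand == "-" else 1
    L = genome.length
    if feat.end >= feat.start:
        loc = SimpleLocation(feat.start - 1, feat.end, strand=strand)
    else:
        parts = [SimpleLocation(feat.start - 1, L, strand=strand),
                 SimpleLocation(0, feat.end, strand=strand)]
        if strand < 0:
            parts = parts[::-1]
        loc = CompoundLocation(parts)
    ftype = {"CDS": "CDS", "repeat": "repeat_region", "hr": "repeat_region",
             "other": "misc_feature"}[feat.kind]
    quals = {k: [str(v)] for k, v in feat.qualifiers.items()}
    quals["locus_tag"] = [feat.locus_tag]
    if feat.kind == "hr":
        quals.setdefault("rpt_family", ["hr"])
    return SeqFeature(loc, type=ftype, qualifiers=quals)


def write_annotation(genome: CircularGenome, features, path: str,
                     format: str = "genbank") -> str:
    """Write the genome and/or its features; round-trip safe for coordinates,
    strands and locus_tags in all three formats."""
    for f in features:
        f.validate(genome)
    if format == "genbank":
        rec = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                        description=genome.origin_note or genome.id)
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = genome.topology
        rec.features = [_seqfeature_from_feature(f, genome) for f in features]
        SeqIO.write([rec], path, "genbank")
    elif format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
            for f in features:
                ftype = {"CDS": "CDS", "repeat": "repeat_region",
                         "hr": "repeat_region", "other": "biological_region"}[f.kind]
                # origin-spanning features written with end > L (circular convention)
                end = f.end if f.end >= f.start else f.end + genome.length
                attrs = [f"ID={f.locus_tag}"]
                if f.kind == "hr":
                    attrs.append("rpt_family=hr")
                for k, v in f.qualifiers.items():
                    if k not in ("ID", "rpt_family"):
                        attrs.append(f"{k}={v}")
                phase = "0" if f.kind == "CDS" else "."
                fh.write("\t".join([genome.id, "baculoscribe", ftype, str(f.start),
                                    str(end), ".", f.strand, phase,
                                    ";".join(attrs)]) + "\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("locus_tag\tstart\tend\tstrand\tkind\n")
            for f in features:
                fh.write(f"{f.locus_tag}\t{f.start}\t{f.end}\t{f.strand}\t{f.kind}\n")
    else:
        raise FormatError(f"unknown output format {format!r}")
    return path
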