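"""Full characterization pipeline: hrs -> ORFs (hr-masked) -> promoters ->
optional comparative/demarcation, with a consolidated JSON report.

hr detection runs first because ORFs lying entirely within hr loci are left
unannotated; the promoter scan runs on the post-masking ORF table.  Every
effective parameter is logged into the report, and reruns with the same
configuration are byte-identical apart from no fields at all (no timestamps
are recorded).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

import yaml

from . import comparative as comp
from . import distances as dist
from .genome import CircularGenome, read_genome, rotate_to_origin, write_annotation
from .hrs import assemble_hrs, find_tandem_repeats, hr_report
from .orfs import (assign_locus_tags, classify_orfs, find_orfs, genome_stats,
                   mask_hr_orfs, orfs_to_features, resolve_overlaps)
from .promoters import classify_promoter, promoter_summary, upstream_window

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "validate_report",
           "annotate_genome"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Pipeline configuration; every default is the paper-derived value
    documented in the corresponding module."""

    genome: str = ""                 # input FASTA/GenBank path
    format: str = "auto"
    topology: str = "circular"
    rotate_to: int | None = None     # 1-based position to become base 1
    outdir: str = "baculoscribe_out"
    tag_prefix: str = "ORF"
    seed: int = 0
    # ORF annotation
    min_aa: int = 50
    max_overlap_bp: int = 75
    start_rule: str = "longest"
    # promoter scan
    window: int = 180
    promoter_loci: list | None = None
    # hr detection
    min_period: int = 50
    max_period: int = 250
    min_copies: float = 2.0
    min_identity: float = 70.0
    min_arm: int = 10
    max_gap: int = 8
    max_mismatch: int = 3
    # homology
    reference_sets: dict | None = None   # class -> {name: protein}
    rbh_min_score: float = 100.0
    rbh_min_identity: float = 25.0
    # optional stages
    genome_b: str | None = None
    run_identity: bool = False
    markers: dict | None = None          # gene -> (seq_query, seq_subject)
    demarcation_threshold: float = 0.05

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineError("config", f"unknown keys {sorted(unknown)}")
        return cls(**data)

    def parameters(self) -> dict:
        d = asdict(self)
        d.pop("reference_sets", None)
        d.pop("markers", None)
        return d


def annotate_genome(genome: CircularGenome, config: RunConfig):
    """hr detection, hr-masked ORF annotation and promoter classification.

    Returns ``(orfs, hr_loci, hr_table, promoter_calls)``.
    """
    arrays = find_tandem_repeats(
        genome.sequence, min_period=config.min_period,
        max_period=config.max_period, min_copies=config.min_copies,
        min_identity=config.min_identity)
    hr_loci = assemble_hrs(arrays, genome, min_arm=config.min_arm,
                           max_gap=config.max_gap,
                           max_mismatch=config.max_mismatch)
    orfs = find_orfs(genome, min_aa=config.min_aa,
                     start_rule=config.start_rule)
    orfs = mask_hr_orfs(orfs, hr_loci, genome.length)
    orfs = resolve_overlaps(orfs, genome.length,
                            max_overlap_bp=config.max_overlap_bp)
    orfs = assign_locus_tags(orfs, prefix=config.tag_prefix)
    if config.reference_sets:
        orfs = classify_orfs(orfs, config.reference_sets,
                             min_score=config.rbh_min_score,
                             min_identity=config.rbh_min_identity)
    hr_table = hr_report(hr_loci, orfs, genome.length)
    loci = (set(config.promoter_loci) if config.promoter_loci else None)
    calls = []
    for orf in orfs:
        if loci is not None and orf.locus_tag not in loci:
            continue
        w = upstream_window(genome, orf, window=config.window)
        calls.append(classify_promoter(w, locus_tag=orf.locus_tag))
    return orfs, hr_loci, hr_table, calls


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle into
    ``config.outdir``.  Returns the report dict."""
    os.makedirs(config.outdir, exist_ok=True)
    try:
        genome, _ = read_genome(config.genome, format=config.format,
                                topology=config.topology)
    except Exception as exc:
        raise PipelineError("input", str(exc)) from exc
    if config.rotate_to:
        genome = rotate_to_origin(genome, config.rotate_to)

    try:
        orfs, hr_loci, hr_table, calls = annotate_genome(genome, config)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("annotate", str(exc)) from exc

    stats = genome_stats(genome, orfs)
    summary = promoter_summary(calls) if calls else {
        "counts": {"early": 0, "late": 0, "both": 0, "none": 0}, "n": 0,
        "mean_tata_cakt_spacing": None, "mean_late_offset": None}

    report = {
        "genome": {"id": genome.id, **stats.as_dict()},
        "parameters": config.parameters(),
        "seed": config.seed,
        "orfs": [{
            "locus_tag": o.locus_tag, "start": o.start, "end": o.end,
            "strand": o.strand, "length_aa": o.length_aa,
            "annotation_class": o.annotation_class,
        } for o in orfs],
        "promoters": {
            **summary,
            "calls": [{
                "locus_tag": c.locus_tag, "class": c.classification,
                "early_hits": [list(h) for h in c.early_hits],
                "tata_like_hits": c.tata_like_hits,
                "late_hits": c.late_hits,
            } for c in calls],
        },
        "hrs": [{k: v for k, v in row.items() if k != "alignment"}
                for row in hr_table],
    }

    # optional comparative stage
    if config.genome_b:
        try:
            genome_b, feats_b = read_genome(config.genome_b)
            cfg_b = RunConfig(**{**config.parameters(), "genome": config.genome_b,
                                 "genome_b": None, "tag_prefix": "B"})
            orfs_b, _, _, _ = annotate_genome(genome_b, cfg_b)
            pairs = comp.reciprocal_best_hits(
                {o.locus_tag: o.translation for o in orfs},
                {o.locus_tag: o.translation for o in orfs_b},
                min_score=config.rbh_min_score,
                min_identity=config.rbh_min_identity)
            order_a = [o.locus_tag for o in sorted(orfs, key=lambda o: o.start)]
            order_b = [o.locus_tag for o in sorted(orfs_b, key=lambda o: o.start)]
            points, rho = comp.parity_points(pairs, order_a, order_b)
            report["comparative"] = {
                "genome_b": genome_b.id,
                "shared_orfs": len(pairs),
                "pairs": [{"a": p.locus_a, "b": p.locus_b,
                           "score": p.score,
                           "identity": round(p.identity, 1)} for p in pairs],
                "parity": [[pt.rank_a, pt.rank_b] for pt in points],
                "spearman_rho": rho,
            }
            if config.run_identity:
                report["comparative"]["whole_genome_identity_percent"] = round(
                    comp.whole_genome_identity(genome, genome_b), 1)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("comparative", str(exc)) from exc

    # optional demarcation stage
    if config.markers:
        try:
            results = {}
            for gene, (qa, qb) in config.markers.items():
                pair = dist.global_align_pair(qa, qb, source_gene=gene)
                results[gene] = dist.k2p_distance(pair)
            report["demarcation"] = dist.demarcation(
                results, threshold=config.demarcation_threshold)
        except Exception as exc:
            raise PipelineError("demarcation", str(exc)) from exc

    _write_outputs(genome, orfs, hr_loci, hr_table, calls, report, config)
    return report


def _write_outputs(genome, orfs, hr_loci, hr_table, calls, report, config):
    out = config.outdir
    feats = orfs_to_features(orfs)
    from .genome import FeatureRecord
    for hr in hr_loci:
        feats.append(FeatureRecord(locus_tag=hr.name, start=hr.start,
                                   end=hr.end, strand="+", kind="hr",
                                   qualifiers={"rpt_type": "tandem"}))
    write_annotation(genome, feats, os.path.join(out, "annotated.gb"),
                     format="genbank")
    write_annotation(genome, feats, os.path.join(out, "annotation.gff3"),
                     format="gff3")
    write_annotation(genome, feats, os.path.join(out, "features.tsv"),
                     format="tsv")
    with open(os.path.join(out, "hrs.bed"), "w") as fh:
        for hr in hr_loci:   # BED is 0-based half-open
            fh.write(f"{genome.id}\t{hr.start - 1}\t{hr.end}\t{hr.name}\n")
    with open(os.path.join(out, "hr_report.txt"), "w") as fh:
        for row in hr_table:
            fh.write(row["alignment"] + "\n\n")
    with open(os.path.join(out, "promoters.tsv"), "w") as fh:
        fh.write("locus_tag\tclass\ttata\tcakt\ttata_like\tlate\n")
        for c in calls:
            tata = ",".join(str(t) for t, _, _ in c.early_hits) or "."
            cakt = ",".join(str(x) for _, x, _ in c.early_hits) or "."
            tl = ",".join(map(str, c.tata_like_hits)) or "."
            lt = ",".join(map(str, c.late_hits)) or "."
            fh.write(f"{c.locus_tag}\t{c.classification}\t{tata}\t{cakt}\t"
                     f"{tl}\t{lt}\n")
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# minimal JSON-schema validation (type/required/properties/items/enum subset)

def _check(obj, schema, path="$"):
    errors = []
    t = schema.get("type")
    typemap = {"object": dict, "array": list, "string": str,
               "integer": int, "number": (int, float), "boolean": bool}
    if t:
        pytype = typemap[t]
        if t == "integer" and isinstance(obj, bool):
            errors.append(f"{path}: expected integer, got bool")
        elif not isinstance(obj, pytype):
            errors.append(f"{path}: expected {t}, got {type(obj).__name__}")
            return errors
    if "enum" in schema and obj not in schema["enum"]:
        errors.append(f"{path}: {obj!r} not in {schema['enum']}")
    if t == "object":
        for key in schema.get("required", []):
            if key not in obj:
                errors.append(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                errors.extend(_check(obj[key], sub, f"{path}.{key}"))
    if t == "array" and "items" in schema:
        for i, item in enumerate(obj):
            errors.extend(_check(item, schema["items"], f"{path}[{i}]"))
    return errors


def validate_report(report: dict) -> list:
    """Validate a report dict against the shipped schema; returns a list of
    error strings (empty when valid)."""
    schema_path = os.path.join(os.path.dirname(__file__), "report_schema.json")
    with open(schema_path) as fh:
        schema = json.load(fh)
    return _check(report, schema)
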