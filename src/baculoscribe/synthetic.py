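"""Seeded synthetic baculovirus-like genomes with exact ground truth.

The generator emits a circular genome with the architecture the pipeline is
designed to characterize — i.i.d. background at a requested G+C, densely
packed >=50-codon ORFs on both strands with planted promoter motifs at
recorded offsets, and hr loci of tandem ~112-bp units with a central
imperfect palindrome — together with a GroundTruth object mapping every
planted feature to its coordinates.

Exactness guarantees (so that recovery tests are sharp, not statistical):

* an in-frame TAA is planted immediately 5' of every planted ATG, so the
  longest-ORF rule starts exactly at the planted start codon;
* upstream windows are scrubbed of chance promoter-motif matches;
* chance background ORFs reaching the length threshold are eliminated by
  seeded stop-codon insertion (synonymous recoding when the chance ORF lies
  inside a planted ORF), so planted ORF recovery is exact at 100%
  precision/recall outside hr loci.

Each feature category draws from its own child random stream, so adding a
feature type does not perturb the other draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome import CircularGenome, reverse_complement
from .orfs import OrfFeature, find_orfs, mask_hr_orfs, STOP_CODONS
from .promoters import (classify_promoter, scan_motif, upstream_window,
                        EARLY_TATA, EARLY_CAKT, TATA_LIKE, LATE_MOTIF)

__all__ = ["OrfPlan", "HrPlan", "GenomeSpec", "GroundTruth", "make_genome",
           "evolve_sequence", "make_ortholog_pair", "paper_shaped_spec"]

BASES = "ACGT"
PAD = 180            # dedicated upstream pad per planted ORF (= window size)
MIN_SPACER = 30
_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
_SENSE_CODONS = [c for c in _CODONS if c not in STOP_CODONS]

# standard genetic code, for synonymous recoding during scrubbing
_CODE = {}
from Bio.Data.CodonTable import standard_dna_table as _tab
for _c, _aa in _tab.forward_table.items():
    _CODE[_c] = _aa
_SYN = {}
for _c, _aa in _CODE.items():
    _SYN.setdefault(_aa, []).append(_c)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class OrfPlan:
    length_aa: int
    strand: str = "+"
    promoter_class: str = "none"   # early | late | both | none


@dataclass
class HrPlan:
    unit_len: int = 112
    copies: int = 3
    palindrome_span: int = 26
    palindrome_mismatches: int = 2
    unit_divergence: float = 5.0   # percent substitutions per copy vs master


@dataclass
class GenomeSpec:
    length_bp: int
    gc_percent: float = 45.0
    orf_plan: list = field(default_factory=list)
    hr_plan: list = field(default_factory=list)
    seed: int = 0
    id: str = "synthetic"


@dataclass
class GroundTruth:
    """Planted-feature coordinates; keys are feature names (ORF_001, hr1...)."""

    orf_coords: dict = field(default_factory=dict)       # name -> (start, end, strand, aa, class)
    promoter_positions: dict = field(default_factory=dict)  # name -> {motif: offsets}
    hr_coords: dict = field(default_factory=dict)        # name -> dict
    planted_distances: dict = field(default_factory=dict)


def paper_shaped_spec(seed: int = 0, length_bp: int = 160_000,
                      n_orfs: int = 140, gc_percent: float = 45.0):
    """A genome spec with the architecture of a Group II alphabaculovirus:
    ~160 kb, ~45% G+C, 140 ORFs on both strands with mixed promoter classes,
    and three hrs of 4/3/2 copies of 112-bp units with a 26-bp palindromic
    core."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    classes = ["early", "late", "both", "none"]
    orf_plan = []
    for i in range(n_orfs):
        aa = int(rng.integers(60, 450))
        strand = "+" if rng.random() < 0.55 else "-"
        pcls = classes[int(rng.integers(0, 4))]
        orf_plan.append(OrfPlan(length_aa=aa, strand=strand,
                                promoter_class=pcls))
    hr_plan = [HrPlan(copies=4), HrPlan(copies=3), HrPlan(copies=2)]
    return GenomeSpec(length_bp=length_bp, gc_percent=gc_percent,
                      orf_plan=orf_plan, hr_plan=hr_plan, seed=seed,
                      id=f"synth{seed}")


# ---------------------------------------------------------------------------
# building blocks

def _bg(rng, n, gc):
    p = np.array([(100 - gc) / 200, gc / 200, gc / 200, (100 - gc) / 200])
    idx = rng.choice(4, size=n, p=p)
    return "".join(BASES[i] for i in idx)


def _chunk_codons(rng, gc, n):
    s = _bg(rng, 3 * max(n, 1), gc)
    return [s[3 * i:3 * i + 3] for i in range(max(n, 1))]


def _draw_motif(rng, motif):
    from .promoters import IUPAC_SETS
    return "".join(s[rng.integers(0, len(s))] if len(s := IUPAC_SETS[c]) > 1
                   else s for c in motif)


def _orf_block(rng_orf, rng_prom, gc, plan: OrfPlan):
    """Coding-strand sense block: [pad(180) incl guard TAA][ATG..stop].
    Returns (block, orf_nt_len, promoter truth dict of offsets)."""
    nt = 3 * (plan.length_aa + 1)
    # codon bases follow the background composition (stops re-drawn) so the
    # coding majority of the genome stays near the requested G+C
    codons = []
    while len(codons) < plan.length_aa - 1:
        for c in _chunk_codons(rng_orf, gc, plan.length_aa - 1 - len(codons)):
            if c not in STOP_CODONS:
                codons.append(c)
    orf_seq = "ATG" + "".join(codons) + STOP_CODONS[int(rng_orf.integers(0, 3))]
    # keep the coding strand of the ORF interior free of promoter motifs
    for _ in range(200):
        hit = None
        for motif in (EARLY_TATA, TATA_LIKE, LATE_MOTIF):
            hits = scan_motif(orf_seq, motif)
            if hits:
                hit = hits[0] + len(orf_seq)
                break
        if hit is None:
            break
        cod = max(1, min((hit // 3), plan.length_aa - 1))
        repl = _SENSE_CODONS[int(rng_orf.integers(0, len(_SENSE_CODONS)))]
        orf_seq = orf_seq[:3 * cod] + repl + orf_seq[3 * cod + 3:]

    pad = list(_bg(rng_orf, PAD - 3, gc) + "TAA")
    truth = {}

    def put(offset, s):
        # offset is signed, -1 = last pad base
        i = PAD + offset
        pad[i:i + len(s)] = list(s)

    if plan.promoter_class in ("early", "both"):
        spacing = int(rng_prom.integers(25, 36))
        lo, hi = (-170, -131) if plan.promoter_class == "both" else (-100, -51)
        tata_off = int(rng_prom.integers(lo, hi + 1))
        tata = _draw_motif(rng_prom, EARLY_TATA)
        cakt = _draw_motif(rng_prom, EARLY_CAKT)
        put(tata_off, tata)
        put(tata_off + spacing, cakt)
        truth["tata"] = tata_off
        truth["cakt"] = tata_off + spacing
        truth["spacing"] = spacing
    if plan.promoter_class in ("late", "both"):
        late_off = int(rng_prom.integers(-80, -39))
        put(late_off, _draw_motif(rng_prom, LATE_MOTIF))
        truth["late"] = late_off
    return "".join(pad) + orf_seq, nt, truth


def _hr_block(rng, gc, plan: HrPlan):
    """Tandem units with a central imperfect palindrome in the master unit;
    per-copy divergence is applied outside the palindromic core so the
    planted mismatch count is preserved in the consensus."""
    span = plan.palindrome_span
    arm = span // 2
    gap = span - 2 * arm
    unit = list(_bg(rng, plan.unit_len, gc))
    # AT-rich wall carrying stop codons in all six frames: keeps hr interiors
    # free of annotatable ORFs (hrs are left unannotated downstream anyway)
    wall = "TTAATTAATTAA"
    unit[0:len(wall)] = list(wall)
    pal_start = (plan.unit_len - span) // 2
    left = _bg(rng, arm, gc)
    right = list(reverse_complement(left))
    mm_pos = rng.choice(arm, size=plan.palindrome_mismatches, replace=False)
    for p in mm_pos:
        cur = right[p]
        choices = [b for b in BASES if b != cur and b != _COMP[left[arm - 1 - p]]]
        right[p] = choices[int(rng.integers(0, len(choices)))]
    core = left + _bg(rng, gap, gc) + "".join(right)
    unit[pal_start:pal_start + span] = list(core)
    master = "".join(unit)
    protected = set(range(pal_start, pal_start + span))
    protected.update(range(len(wall)))
    copies = []
    n_mut = int(round(plan.unit_divergence / 100.0 * plan.unit_len))
    for _ in range(plan.copies):
        cp = list(master)
        sites = [i for i in range(plan.unit_len) if i not in protected]
        if n_mut and sites:
            chosen = rng.choice(len(sites), size=min(n_mut, len(sites)),
                                replace=False)
            for ci in chosen:
                i = sites[int(ci)]
                alt = [b for b in BASES if b != cp[i]]
                cp[i] = alt[int(rng.integers(0, 3))]
        copies.append("".join(cp))
    return "".join(copies), master


# ---------------------------------------------------------------------------
# genome assembly + scrubbing

class _Editor:
    """Mutable genome with positional write-protection."""

    def __init__(self, seq: str):
        self.seq = list(seq)
        self.L = len(seq)
        self.locked = set()        # 0-based positions that must never change
        self.codon_lock = {}       # 0-based pos -> (orf_key,)

    def lock(self, start0, n):
        self.locked.update((start0 + k) % self.L for k in range(n))

    def __str__(self):
        return "".join(self.seq)


def _orf_feature(name, start, end, strand, aa):
    return OrfFeature(locus_tag=name, start=start, end=end, strand=strand,
                      length_aa=aa, frame=(start - 1) % 3, translation="")


def _coding_pos(orf, k, L):
    """0-based plus position of coding-strand offset k of a planted span."""
    if orf[2] == "+":
        return (orf[0] - 1 + k) % L
    return (orf[1] - 1 - k) % L


def _window_ok(genome, truth, name, orf):
    """Does the upstream window of a planted ORF contain exactly its planted
    motifs (plus any CAKT the classifier would ignore)?"""
    w = upstream_window(genome, _orf_feature(name, *orf[:3], orf[3]))
    call = classify_promoter(w, name)
    planted = truth.promoter_positions.get(name, {})
    want = orf[4]
    if call.classification != want:
        return False
    hits = {"tata": scan_motif(w, EARLY_TATA), "cakt": scan_motif(w, EARLY_CAKT),
            "tata_like": scan_motif(w, TATA_LIKE), "late": scan_motif(w, LATE_MOTIF)}
    for key in ("tata", "cakt"):
        expect = [planted[key]] if key in planted else []
        if hits[key] != expect:
            return False
    if hits["tata_like"]:
        return False
    expect_late = [planted["late"]] if "late" in planted else []
    if hits["late"] != expect_late:
        return False
    return True


def _scrub_windows(ed: _Editor, truth: GroundTruth, rng) -> bool:
    """Remove chance motif matches from every planted upstream window.
    Returns True when all windows are clean."""
    genome = CircularGenome(id="tmp", sequence=str(ed))
    L = ed.L
    all_clean = True
    for name, orf in sorted(truth.orf_coords.items()):
        if _window_ok(genome, truth, name, orf):
            continue
        all_clean = False
        feat = _orf_feature(name, *orf[:3], orf[3])
        w = upstream_window(genome, feat)
        planted = truth.promoter_positions.get(name, {})
        planted_spans = set()
        for key, motif in (("tata", EARLY_TATA), ("cakt", EARLY_CAKT),
                           ("late", LATE_MOTIF)):
            if key in planted:
                planted_spans.update(range(planted[key],
                                           planted[key] + len(motif)))
        for motif in (EARLY_TATA, EARLY_CAKT, TATA_LIKE, LATE_MOTIF):
            for off in scan_motif(w, motif):
                if off in (planted.get("tata"), planted.get("cakt"),
                           planted.get("late")):
                    continue
                # disrupt one editable base of this chance hit
                cand = [off + j for j in range(len(motif))
                        if (off + j) not in planted_spans]
                rng.shuffle(cand)
                for o in cand:
                    if orf[2] == "+":
                        pos0 = (orf[0] - 1 + o) % L
                    else:
                        pos0 = (orf[1] - 1 - o) % L
                    if pos0 in ed.locked or pos0 in ed.codon_lock:
                        continue
                    # C breaks every letter of all four motifs except CAKT's C;
                    # pick a base differing from the motif requirement
                    j = o - off
                    from .promoters import IUPAC_SETS
                    allowed = IUPAC_SETS[motif[j]]
                    repl = [b for b in BASES if b not in allowed]
                    c = repl[int(rng.integers(0, len(repl)))]
                    ed.seq[pos0] = c if orf[2] == "+" else _COMP[c]
                    break
    return all_clean


def _break_orf(ed: _Editor, truth: GroundTruth, orf: OrfFeature, min_aa, rng):
    """Destroy a chance ORF by planting an in-frame stop.

    Planted translations are not part of the ground truth, so interior
    codons of planted ORFs may be recoded to any *sense* codon; only start,
    stop and guard codons, planted motifs and hr loci are inviolable.  Every
    candidate edit is validated against the planted upstream windows it
    touches.
    """
    L = ed.L
    span = (orf.start, orf.end, orf.strand)
    n_codons = orf.length_aa + 1
    interior = list(range(1, n_codons - 1))
    rng.shuffle(interior)
    for k in interior:
        pos = [_coding_pos(span, 3 * k + j, L) for j in range(3)]
        if any(p in ed.locked for p in pos):
            continue
        for stop in rng.permutation(list(STOP_CODONS)):
            # desired plus-strand bases of this codon
            want = {p: (c if orf.strand == "+" else _COMP[c])
                    for p, c in zip(pos, stop)}
            # overlapping planted-ORF codons must stay sense codons
            ok = True
            for p in pos:
                key = ed.codon_lock.get(p)
                if key is None:
                    continue
                pname, cidx = key
                porf = truth.orf_coords[pname]
                cpos = [_coding_pos(porf, 3 * cidx + j, L) for j in range(3)]
                new = "".join(
                    (want.get(q, ed.seq[q]) if porf[2] == "+"
                     else _COMP[want.get(q, ed.seq[q])]) for q in cpos)
                if new in STOP_CODONS:
                    ok = False
                    break
            if not ok:
                continue
            old = {p: ed.seq[p] for p in pos}
            for p, c in want.items():
                ed.seq[p] = c
            # guard the edit against corrupting a planted upstream window
            bad = False
            genome = None
            for name, porf in sorted(truth.orf_coords.items()):
                wstart = porf[0] - 1 - PAD if porf[2] == "+" else porf[1]
                wpos = {(wstart + t) % L for t in range(PAD)}
                if any(p in wpos for p in pos):
                    genome = genome or CircularGenome(id="tmp", sequence=str(ed))
                    if not _window_ok(genome, truth, name, porf):
                        bad = True
                        break
            if bad:
                for p, c in old.items():
                    ed.seq[p] = c
                continue
            return True
    return False


def make_genome(spec: GenomeSpec, min_aa: int = 50):
    """Generate a circular genome and its ground truth from a spec.

    Deterministic: identical spec + seed give byte-identical output.
    Raises ValueError when the planned features cannot be packed.
    """
    ss = np.random.SeedSequence(spec.seed)
    streams = {name: np.random.default_rng(np.random.SeedSequence(
        spec.seed, spawn_key=(i,)))
        for i, name in enumerate(["background", "orf", "promoter", "hr",
                                  "placement", "scrub"])}
    truth = GroundTruth()

    # interleave hr blocks among the ORF blocks at evenly spaced indices
    items = [("orf", p if isinstance(p, OrfPlan) else OrfPlan(*p))
             for p in spec.orf_plan]
    hr_items = [("hr", p if isinstance(p, HrPlan) else HrPlan(*p))
                for p in spec.hr_plan]
    if hr_items:
        step = max(1, len(items) // (len(hr_items) + 1))
        for i, h in enumerate(hr_items, 1):
            items.insert(min(i * step + i - 1, len(items)), h)

    blocks = []
    for kind, plan in items:
        if kind == "orf":
            block, nt, ptruth = _orf_block(streams["orf"], streams["promoter"],
                                           spec.gc_percent, plan)
            if plan.strand == "-":
                # plus-strand layout of a minus ORF: [orf_rc][pad_rc]
                block = reverse_complement(block)
            blocks.append(("orf", plan, block, nt, ptruth))
        else:
            block, master = _hr_block(streams["hr"], spec.gc_percent, plan)
            blocks.append(("hr", plan, block, len(master), None))

    total_blocks = sum(len(b[2]) for b in blocks)
    n_gaps = len(blocks) + 1
    extra = spec.length_bp - total_blocks - MIN_SPACER * n_gaps
    if extra < 0:
        raise ValueError(
            f"cannot pack {total_blocks} bp of features (+{MIN_SPACER}-bp "
            f"spacers) into {spec.length_bp} bp")
    shares = streams["placement"].multinomial(extra, [1.0 / n_gaps] * n_gaps)
    spacers = [MIN_SPACER + int(s) for s in shares]

    parts = []
    pos = 0
    planted = []   # (kind, plan, start0, length, ...)
    for i, b in enumerate(blocks):
        sp = _bg(streams["background"], spacers[i], spec.gc_percent)
        parts.append(sp)
        pos += len(sp)
        parts.append(b[2])
        planted.append((b, pos))
        pos += len(b[2])
    parts.append(_bg(streams["background"], spacers[-1], spec.gc_percent))
    seq = "".join(parts)
    assert len(seq) == spec.length_bp

    ed = _Editor(seq)
    n_orf = n_hr = 0
    for (kind, plan, block, nt_or_period, ptruth), start0 in planted:
        if kind == "orf":
            n_orf += 1
            name = f"ORF_{n_orf:03d}"
            if plan.strand == "+":
                orf_start0 = start0 + PAD
                start, end = orf_start0 + 1, orf_start0 + nt_or_period
            else:
                start, end = start0 + 1, start0 + nt_or_period
            truth.orf_coords[name] = (start, end, plan.strand,
                                      plan.length_aa, plan.promoter_class)
            if ptruth:
                truth.promoter_positions[name] = ptruth
            # lock start and stop codons; codon-lock the interior
            span = (start, end, plan.strand)
            ed.lock(_coding_pos(span, 0, ed.L), 1)
            for j in range(3):
                ed.locked.add(_coding_pos(span, j, ed.L))
                ed.locked.add(_coding_pos(span, nt_or_period - 3 + j, ed.L))
            for c in range(1, plan.length_aa):
                for j in range(3):
                    ed.codon_lock[_coding_pos(span, 3 * c + j, ed.L)] = (name, c)
            # lock the guard stop and the planted motifs
            guard0 = (start0 + PAD - 3) if plan.strand == "+" else \
                (start0 + nt_or_period)
            ed.lock(guard0, 3)
            if ptruth:
                for key, motif in (("tata", EARLY_TATA), ("cakt", EARLY_CAKT),
                                   ("late", LATE_MOTIF)):
                    if key in ptruth:
                        for j in range(len(motif)):
                            o = ptruth[key] + j
                            if plan.strand == "+":
                                ed.locked.add((start - 1 + o) % ed.L)
                            else:
                                ed.locked.add((end - 1 - o) % ed.L)
        else:
            n_hr += 1
            name = f"hr{n_hr}"
            hr_len = len(block)
            truth.hr_coords[name] = {
                "start": start0 + 1, "end": start0 + hr_len,
                "period": nt_or_period, "copies": plan.copies,
                "palindrome_span": plan.palindrome_span,
                "palindrome_mismatches": plan.palindrome_mismatches,
            }
            ed.lock(start0, hr_len)

    # iterative scrubbing: windows clean of chance motifs, genome clean of
    # chance ORFs outside hr loci
    rng = streams["scrub"]
    hr_spans = [_HrSpan(d["start"], d["end"])
                for d in truth.hr_coords.values()]
    planted_keys = {(v[0], v[1], v[2]) for v in truth.orf_coords.values()}
    for _ in range(60):
        windows_clean = _scrub_windows(ed, truth, rng)
        genome = CircularGenome(id=spec.id, sequence=str(ed))
        found = find_orfs(genome, min_aa=min_aa)
        found = mask_hr_orfs(found, hr_spans, ed.L)
        spurious = [o for o in found
                    if (o.start, o.end, o.strand) not in planted_keys]
        if windows_clean and not spurious:
            break
        for orf in spurious:
            _break_orf(ed, truth, orf, min_aa, rng)
    else:
        warnings.warn("scrubbing did not fully converge; ground truth may "
                      "not be exactly recoverable")

    genome = CircularGenome(id=spec.id, sequence=str(ed),
                            origin_note="synthetic genome, position 1 arbitrary")
    return genome, truth


@dataclass
class _HrSpan:
    start: int
    end: int


# ---------------------------------------------------------------------------
# marker-gene evolution under the Kimura 2-parameter process

def evolve_sequence(seq: str, target_distance: float,
                    ts_tv_ratio: float = 2.0, seed: int = 0) -> str:
    """Substitute sites under the K2P process so the expected K2P distance
    equals ``target_distance`` (no indels).

    ``ts_tv_ratio`` is kappa = alpha/beta, the ratio of the transition rate
    to each of the two transversion rates (equivalently alpha/(2 beta) =
    ts_tv_ratio/2 for the pooled transversion rate).  Site fates are drawn
    from the exact finite-time K2P transition probabilities.
    """
    if not 0.0 <= target_distance <= 1.0:
        raise ValueError("target_distance must be in [0, 1]")
    if target_distance == 0.0:
        return seq
    kappa = ts_tv_ratio
    bt = target_distance / (kappa + 2.0)   # beta * t
    at = kappa * bt                        # alpha * t
    e4b = np.exp(-4.0 * bt)
    e2ab = np.exp(-2.0 * (at + bt))
    p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab
    p_tv = 0.5 - 0.5 * e4b                 # both transversion targets pooled
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    u = rng.random(len(seq))
    which = rng.integers(0, 2, size=len(seq))   # transversion target choice
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    transversions = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
    out = []
    for i, b in enumerate(seq.upper()):
        if b not in transition:
            out.append(b)
        elif u[i] < p_ts:
            out.append(transition[b])
        elif u[i] < p_ts + p_tv:
            out.append(transversions[b][which[i]])
        else:
            out.append(b)
    return "".join(out)


def make_ortholog_pair(n_genes: int, identity_target: float, seed: int = 0,
                       n_decoys: int | None = None):
    """Two synthetic proteomes with a known ortholog pairing.

    ``n_genes`` orthologous proteins are copied from proteome A to B with
    substitutions bringing them to ``identity_target`` percent identity;
    ``n_decoys`` unrelated random proteins (default ``n_genes // 2``) are
    added to each side.  Returns ``(proteome_a, proteome_b, truth)`` where
    truth maps A locus -> B locus.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_decoys is None:
        n_decoys = n_genes // 2
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(11,)))
    aas = "ACDEFGHIKLMNPQRSTVWY"

    def protein(n):
        return "".join(aas[i] for i in rng.integers(0, 20, size=n))

    proteome_a, proteome_b, truth = {}, {}, {}
    for i in range(1, n_genes + 1):
        n = int(rng.integers(100, 301))
        p = protein(n)
        n_sub = int(round((1.0 - identity_target / 100.0) * n))
        q = list(p)
        if n_sub:
            sites = rng.choice(n, size=n_sub, replace=False)
            for s in sites:
                alt = [a for a in aas if a != q[s]]
                q[s] = alt[int(rng.integers(0, 19))]
        la, lb = f"A_{i:03d}", f"B_{i:03d}"
        proteome_a[la] = p
        proteome_b[lb] = "".join(q)
        truth[la] = lb
    for i in range(1, n_decoys + 1):
        proteome_a[f"Adecoy_{i:03d}"] = protein(int(rng.integers(100, 301)))
        proteome_b[f"Bdecoy_{i:03d}"] = protein(int(rng.integers(100, 301)))
    return proteome_a, proteome_b, truth
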