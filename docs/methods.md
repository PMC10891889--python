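# Methods

This note records the models, conventions and numerical choices behind
`baculoscribe`, and what its green tests do and do not establish.

## Coordinates and topology

All feature coordinates are 1-based inclusive (the GenBank convention).
On a circular genome a feature with `end < start` spans the origin; it is
written as `join(start..L,1..L..end)` in GenBank output and with
`end + L` in GFF3 (the circular-genome convention). Overlaps between
features — including features on opposite strands — are measured on
plus-strand projected intervals, circularly. `rotate_to_origin` supports
the field's convention of placing the polyhedrin start codon at the top
of the physical map; the rotation position is the caller's choice because
deposited records differ in whether "position 1" or "position 0" anchors
the polh ATG.

Ambiguity codes (N etc.) are retained on input but never match a motif,
never count as an alignment match, and are excluded from G+C and from
K2P site counts.

## ORF model

An ORF is an open reading frame from an ATG to the first in-frame stop,
encoding ≥ `min_aa` (default 50) amino acids. The default start rule is
*longest*: within each stop-bounded segment the most-upstream ATG is
reported. A *shortest* rule (most-downstream ATG still meeting the
length minimum) is available behind a flag, because published gene
catalogues built with multiple predictors do not always state which
variant survived curation. The circular scan runs on a tripled copy of
the sequence — that guarantees every wrap ORF appears in some linear copy
together with both its bounding upstream stop and its own stop codon —
and deduplicates by modular coordinates; ORFs longer than the genome
(no stop in frame) are not reported.

Overlap resolution drops the smaller ORF of every pair overlapping by
more than `max_overlap_bp` (default 75) unless the smaller one is flagged
as a conserved homolog; an exact 75-bp overlap keeps both. Equal-length
ties keep the plus-strand ORF, then the lower start coordinate (the
convention is unstated in the literature; a deterministic tie-break was
required). ORFs lying *entirely* inside an hr locus are removed after hr
detection; partial overlaps are kept. Hence pipeline order: hrs first,
then the final ORF table, then promoters.

The coding fraction is computed on the union of ORF spans (overlaps
counted once, both strands projected to plus), and G+C excludes
ambiguous bases from numerator and denominator.

## Promoter model

The 180-nt window 5′ of each initiation codon, on the coding strand
only, is scanned for four IUPAC motifs: TATAW and CAKT (early, the CAKT
start site 25–35 nt downstream of the TATA — measured motif start to
motif start, bounds inclusive, since the anchor point is conventionally
left unstated), TAATWAA (TATA-like, counts as early evidence on its
own), and DTAAG (late). Positions are signed offsets with −1 the base
adjacent to the A of ATG. On a circular genome the window wraps but is
capped at `genome length − ORF length` so it cannot run through the ORF
itself; on linear sequence it truncates with a warning.

The summary reports class counts (early/late/both/none always partition
the input), the mean TATA→CAKT spacing over all early hits, and the mean
DTAAG offset with one representative hit per ORF — the hit closest to
the start codon, over every ORF whose window contains the late element
(classes late *and* both). Antisense promoter elements are not searched.

## hr model

Homologous regions are modelled as tandem arrays of ~50–250-bp units
whose consensus carries an imperfect palindromic core near the unit
centre. Detection is a re-implementation at the hr scale, not a port of
the published tandem-repeats-finder probability model (whose parameters
the descriptive literature does not give):

1. **Period estimate** — modal distance between consecutive occurrences
   of shared 12-mers within the period band.
2. **Boundary refinement** — on the periodic self-match profile
   `m[i] = [seq[i] == seq[i+p]]`, the array is extended outward from the
   k-mer seed region in 12-bp steps while the windowed match fraction
   stays ≥ 0.5, then fine-extended/trimmed base by base. For exact
   repeats this recovers boundaries exactly; at ≤ 10% unit divergence the
   boundaries are within a few bp and copy number is exact.
3. **Units and consensus** — units are cut at the period from the array
   start; the consensus is a per-column majority vote with ties resolved
   toward the first unit; edge units under the identity floor (70%) are
   trimmed. Overlapping candidates merge, keeping the higher copy number.
4. **Palindrome gate** — an array becomes an hr iff `find_palindromes`
   (arms ≥ 10, loop ≤ 8, mismatches ≤ 3 by default — chosen to admit a
   26-bp imperfect core and exposed as options, since the original
   EMBOSS-style parameters are unstated) reports a palindrome whose
   centre lies in the central third of the consensus. The palindrome
   search runs on the unit consensus directly rather than on
   genome-coordinate palindrome lists; tightening the mismatch budget can
   only remove hr calls (tested monotonicity).

AT content is annotated on every hr but never used as a filter; hr
AT-richness is a qualitative, not quantitative, character. Palindrome
arms end on a matching pair (trailing mismatches are trimmed), which
makes the finder strand-symmetric. hr detection runs on the linearized
sequence; an hr crossing the chosen origin would need a prior rotation.

## K2P distances and demarcation

For an aligned pair, sites with a gap or N in either sequence are
excluded (pairwise deletion — "missing data" semantics combined with
pairwise computation); P and Q are the transition (A↔G, C↔T) and
transversion proportions over the remaining sites, and
`d = −½ ln[(1−2P−Q)√(1−2Q)]` with uniform rates across sites. Zero
comparable sites raises `UndefinedDistanceError`; saturation
(`1−2P−Q ≤ 0` or `1−2Q ≤ 0`) returns `defined=False` with a NaN
distance rather than an exception, so matrix construction survives
distant pairs. The demarcation verdict is *novel* iff every provided
marker distance strictly exceeds the threshold (default
0.05 substitutions/site), *not_novel* iff all are ≤ it, otherwise
*inconclusive*; missing canonical markers (polh/lef8/lef9) are listed
but do not block a verdict.

Marker pairs are aligned with the package's own affine-gap global
aligner (match 5, mismatch −4, gap open −10, gap extend −0.5) rather
than an external multiple aligner, keeping the pipeline dependency-free;
the alignment parameters are recorded in output because the choice of
aligner perturbs distances slightly.

## Alignment engine

One gap-cost convention is used package-wide: a gap run of length L
costs `open + (L−1)·extend` (EMBOSS convention). Global DNA alignment
uses Gotoh's three-state recursion driven by a Myers–Miller
divide-and-conquer, so memory stays linear in sequence length; leaf
subproblems (≤ ~2000 cells) run the quadratic traceback DP. Traceback
tie-breaks are deterministic: diagonal over gap, then gap in the first
sequence. The linear-space score is verified against a full-matrix
oracle and against Biopython's `PairwiseAligner` on fuzzed instances.
Whole-genome identity uses stretcher-style scoring (5/−4, gap open 16,
extend 4) and reports identical columns over the full alignment length.
The *score* is exactly symmetric in the two inputs; the reported
*identity* can differ in the last decimal between orientations when
several alignments tie for the optimum.

Protein local alignment (BLOSUM62, gap open −11 extend −1 under the same
convention) is delegated to Biopython's C implementation; a pure-Python
Smith–Waterman oracle in the test suite checks it independently.

## Homology and collinearity

Homologs are reciprocal best hits (RBH) under exact all-vs-all local
alignment — tractable for ~150-protein viral proteomes and free of
E-value/database-size dependence. The score floor (default 100) was
calibrated on a shuffled-residue decoy null: across fixed-seed decoy
proteomes the best random score stays below ~90, so the default yields
zero null pairs while genuine homologs down to ~40% identity score in
the hundreds. Because the cutoffs behind published shared-ORF counts
are never stated, RBH counts against real comparator genomes are
reported, not asserted.

Parity ranks are ordinal gene positions by ascending start coordinate
from each genome's (rotated) origin; collinearity is summarized by the
Spearman rank correlation of the homolog ranks. Whole-genome identity
is computed once, plus strand vs plus strand, after both genomes are
rotated to their polyhedrin origin; no reverse-strand trial is made.
Core-gene presence is an RBH check of a user-supplied reference protein
per family (the canonical 38 baculovirus core genes are names, not
sequences, in this package — users supply the sequences). Supermatrix
concatenation preserves input family order and emits a RAxML-style
partition table; tree inference itself is out of scope.

## Synthetic genomes: the stated world

`paper_shaped_spec` encodes the genome architecture the pipeline
targets: 160 kb, 45% G+C, 140 ORFs of 60–450 aa (~55% forward strand)
with promoter classes drawn uniformly from early/late/both/none, and
three hrs of 4/3/2 copies of 112-bp units, each with a 26-bp central
palindrome carrying 2 mismatches and 5% per-copy divergence outside the
core. Promoter motifs are planted at recorded offsets (TATAW uniformly
in −100…−51, spacing uniform in 25…35; DTAAG uniform in −80…−40; for
"both" the early element moves to −170…−131 so the motifs cannot
collide). Background is i.i.d. at the requested G+C — sufficient for
motif/repeat null behaviour and trivially verifiable; coding regions
draw codon bases from the same composition (stops re-drawn).

Three constructions make recovery *exact* rather than statistical:

* an in-frame TAA guard directly 5′ of every planted ATG pins the
  longest-ORF rule to the planted start;
* each repeat unit begins with an AT-rich 12-bp wall (`TTAATTAATTAA`)
  containing stops in all six frames, so no ≥ 50-codon frame survives
  inside or across an hr (hr-interior ORFs are unannotatable by design
  anyway, and the wall makes hrs realistically AT-rich);
* after assembly, a seeded scrubbing loop (its own random stream)
  removes chance promoter-motif matches from every upstream window and
  chance ≥ 50-aa ORFs from the whole genome by inserting stop codons —
  recoding interior codons of planted ORFs to other *sense* codons where
  necessary (planted translations are not part of the ground truth;
  coordinates, classes and motif offsets are). Each edit is validated
  against every planted window it touches.

Each feature category (background, ORF codons, promoters, hrs,
placement, scrubbing) draws from its own child stream of the spec seed,
so output is byte-identical across runs and adding a feature type does
not shift other draws.

What the generator does *not* emulate: dinucleotide/codon-usage
structure, gene-length and strand clustering of real baculovirus
genomes, transposon-like insertions, indel evolution in markers, and a
realistic (~83%) coding density — each planted ORF carries a dedicated
180-bp promoter pad, which caps coding fraction near 70% at the default
shape. A green recovery test therefore establishes correctness of the
coordinate arithmetic, scanning and detection logic under the planted
model, not performance on real genomes.

`evolve_sequence` applies the exact finite-time K2P substitution
probabilities per site (no indels): for target distance d and
κ = α/β (`ts_tv_ratio`, default 2), βt = d/(κ+2), αt = κβt,
`P(t) = ¼ + ¼e^{−4βt} − ½e^{−2(α+β)t}`, `Q(t) = ½ − ½e^{−4βt}`. The
plug-in K2P estimator then has expectation d by construction; the test
suite verifies estimator recovery at d ∈ {0.05, 0.1, 0.3} (10 kb,
50 seeds, within 3 standard errors) and two-step additivity.

## Pipeline and report

`run_pipeline` executes hr detection → hr-masked ORF annotation →
overlap resolution → locus-tag assignment → promoter census → optional
comparative and demarcation stages, writes GenBank/GFF3/TSV/BED/TSV
outputs plus `report.json`, validates the report against a shipped JSON
schema (a minimal built-in validator covering type / required /
properties / items / enum), and logs every effective parameter in the
report itself. No timestamps are recorded, so reruns with the same
configuration are byte-identical.

## Known limitations

* hr detection assumes substitution-style unit divergence; units
  diverged by indels would shift the period estimate and unit phase.
* Whole-genome alignment is O(n·m) time in Python/NumPy — minutes for
  hundreds of kb; it is intended for the one-shot identity figure, not
  for screening.
* The promoter census is motif-based only; it neither predicts
  transcription starts nor expression timing.
* Demarcation accepts whatever marker fragments the user supplies; the
  verdict is only as comparable as the fragments are.
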