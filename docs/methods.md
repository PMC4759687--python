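# Methods

This note documents the models and procedures implemented in `prfscan`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one reasonable choice
existed.

## Genetic code and sequence model

Translation uses the Euplotid nuclear code (NCBI table 10): UGA → Cys, stops
restricted to UAA/UAG.  The table is constructed locally from the standard
code string with the single TGA reassignment and is cross-checked in the test
suite against Biopython's registry.  Codons containing N translate to X and
never count as stops — a deliberately conservative treatment of assembly
ambiguity, since a spurious stop call at an ambiguous base could either
fabricate or destroy a slippery-site call.

Coordinates are 0-based half-open everywhere in memory; report files use
1-based inclusive coordinates (the BLAST convention).  Frames are offsets
{0, 1, 2} on the forward strand; reverse-orientation hits carry their
coordinates on the reverse complement, and the pipeline re-orients the
transcript before site scanning so all downstream arithmetic is
forward-frame.

ORFs are maximal stop-to-stop (or sequence-edge) runs per frame; a
terminated ORF's coordinates include its stop codon, and its protein
excludes it.  Ties for "longest" break by smaller start, then smaller frame.

## Translated homology search

The internal aligner is an affine-gap Smith–Waterman over BLOSUM62 (gap open
11, extend 1 — the BLASTP/BLASTX defaults), implemented as a numba-compiled
kernel with full traceback.  Each transcript frame is translated in full
(stops kept as `*`, which scores −4 against every residue, so alignments do
not cross in-frame stops unless flanking similarity pays for it — the same
behaviour BLASTX exhibits).  Multiple HSPs per frame come from iterated
alignment with masking: report the best local alignment, overwrite its query
residues with a sentinel that cannot match, repeat while the raw score stays
≥ `min_score` (default 50).

E-values use the Karlin–Altschul formula E = K·m·n·e^(−λS) with the ungapped
BLOSUM62 parameters λ = 0.3176, K = 0.134 applied to gapped scores.  This is
an acknowledged approximation (gapped parameters would be slightly smaller);
raw-score thresholding is the primary filter and the E-value cutoff (1e−5)
is applied on top.  Users with real BLASTX output bypass the internal
aligner entirely via the 13-column `outfmt6_qframe` reader.

The all-vs-all search prescreens (transcript, protein) pairs with shared
amino-acid 4-mers (any frame, count ≥ 3) before aligning exactly.  At the
identity levels the pipeline targets (tens of identical residues per
fragment) the prescreen is effectively lossless; it makes the search
near-linear instead of quadratic.

## Frame-split candidates and junction geometry

A candidate is a pair of HSPs on the same (transcript, protein, orientation)
with different frames, both passing the E-value cutoff, whose interval
centers strictly increase in both query and subject space, whose subject
coverage advances by ≥ 5 aa, and whose query gap is ≤ 200 nt (a scale chosen
for the short UTR/intergenic distances of gene-sized nanochromosomes; all
are config keys).

Centers — not endpoints — are compared for a reason that shaped much of the
design: at ~31% coding GC the proteome is AT-rich and low-complexity
(K/N/I/F-heavy), and a frame-shifted reading of such sequence still aligns
to the protein at 70–85% identity.  HSP *ends* therefore routinely overshoot
the true junction by dozens of residues in the wrong frame, while the
junction-distal anchors (upstream hit start, downstream hit end) remain
exact.  Three consequences:

* **Junction bounds** are projected from subject coordinates: from each
  hit's distal anchor, walk the ungapped diagonal to where the two hits'
  subject coverage meets.  The slippery-stop scan covers these bounds ± the
  slacks (30 nt each side, mirroring the ±30 nt logo window) rather than
  trusting `upstream.q_end`.
* **Diagonal offset.**  The quantity
  `(down.q_end − 3·down.s_end) − (up.q_start − 3·up.s_start)` measures how
  many extra query nucleotides separate the two alignment diagonals: ~1 for
  a genuine +1 frameshift, ~the intron length for a retained intron.  It is
  insensitive to end overshoot.
* **No hard subject-overlap cap** by default (`max_s_overlap=None`), since
  overshoot creates large but harmless overlaps; the center and advance
  rules carry the ordering constraints.

When several hit pairs qualify for the best-scoring subject, the pipeline
processes the pair whose upstream hit starts earliest in the protein — the
initial reading frame's junction — so genes requiring two successive shifts
are entered from the correct end.

## Intron-retention exclusion

Retained introns also split homology across frames and must be removed
before any slippery-stop interpretation.  The heuristic flags a candidate
when the junction region contains a segment that (a) starts GT and ends AG,
(b) has length within [25, 500] nt, (c) is congruent to the observed frame
change mod 3, and (d) matches the diagonal offset to within 15 nt.
Condition (d) is what makes the test discriminative: it demands that the
putative intron actually *explain* the displacement between the two
alignment diagonals, not merely the frame residue — without it, chance
GT..AG pairs (abundant in AT-rich sequence) flag a large fraction of genuine
frameshift genes.  A user-supplied junction table (from a spliced-alignment
run) short-circuits the sequence heuristic.  The 15 nt tolerance absorbs
alignment-gap fuzz in the anchors; introns within 15 nt of length of a
competing explanation are beyond the resolution of a homology-only method.

## Slippery-stop scan, fs-gene, validation

The scan walks the upstream frame codon-by-codon across the junction region
and takes the **first** in-frame UAA/UAG — the operational reading of
"the stop codon was searched in the initial open reading frame", and
consistent with translation: the ribosome meets the first stop first.  The
site record keeps the P-site codon, the stop, the 3′-context nucleotide
(the release-factor tetranucleotide), the motif class (`XXX-TAR`) and a
66-nt window (30 nt flanks around the 6-nt motif, N-padded at sequence
edges).

The fs-gene deletes the T of the stop.  Its protein is the ORF **in the
upstream hit's reading frame** containing the deletion position — the frame
is dictated by the candidate's arithmetic, so this is deterministic; a pure
"longest ORF through the junction" rule could be hijacked by a chance
stop-free run in another frame of low-complexity sequence.

Validation re-aligns the fs-gene to the subject.  A call is confirmed iff
the best post-deletion hit covers ≥ 80% (`min_span`) of the union of the two
original hits' subject intervals and extends ≥ 10 aa (`min_extension`)
beyond the upstream hit's subject end — the operationalization of "a
C-terminally extended protein was produced".  Both are config keys; 10 aa is
small enough to keep short C-terminal segments callable and large enough
that single spurious residues cannot confirm.  Only frame_delta = 1
candidates are callable (+1 by definition; delta = 2 patterns are reported
as `rejected_wrong_delta` — no −1 event is modeled).  After a confirmation
the pipeline re-runs search/scan/validation on the fs-gene (up to 3 sites
per transcript), allowing genes with two successive +1 shifts; secondary
site positions are mapped back to original transcript coordinates.

Detection contains no randomness: identical inputs and config give
byte-identical outputs, and results are independent of transcript processing
order.

## Stop-usage, logo and expression statistics

* "Normal" stops are the terminating stops of the longest ORFs (≥ 30 aa) of
  non-frameshifted transcripts; "slippery" stops are the confirmed sites.
  Which denominator to use for the normal class is genuinely open; longest
  ORFs of non-called transcripts is the choice here and is stated wherever
  the numbers are reported.  A stop occupying the final 3 nt of its
  transcript has no 3′ context: it enters the trinucleotide counts and a
  separate `n_excluded_no_context` tally.
* The Fisher exact test is two-sided by the point-probability rule (sum of
  hypergeometric probabilities ≤ that of the observed table, relative
  tolerance 1e−7 on the tie comparison), computed as a vectorized log-gamma
  pmf summation.  The doubling convention is *not* used; the choice is
  stated because the two conventions differ.
* Logo information content is 2 − H per position over observed A/C/G/T
  frequencies, no pseudocounts and no small-sample correction (matching the
  default behaviour of the common web logo tools); N-only positions are
  reported as missing.  The IUPAC consensus covers all bases with frequency
  ≥ 0.25 per position.
* The expression comparison is a two-sided Welch t-test by default
  (`equal_var=False`); a pooled-variance option exists because the method
  description this mirrors says only "t test".

## The synthetic-data generator

The generator emulates the *structure* of an AT-rich ciliate macronuclear
dataset; its defaults are the study conditions used throughout the tests:

| parameter | default | rationale |
|---|---|---|
| n_transcripts | 500 | desk-scale benchmark size |
| prf_fraction | 0.11 | frameshift-gene fraction of the modeled system |
| motif distribution | AAA .943, TTT .020, AAG .015, AAT .011, ATT .011 | classical motif dominates; novel classes in their observed order |
| stop distribution | slippery UAA .894 / normal UAA .796 | slippery stops more UAA-skewed |
| 3′-context | slippery favours A (.55); normal A .40/T .38 | UAA-A enrichment at slippery sites |
| coding / noncoding GC | 0.31 / 0.23 | exon vs intron/UTR composition of the modeled genome |
| protein length | 120–260 aa | keeps both homology segments ≥ ~40 aa |
| intron decoys / random decoys | 0.05 / 0.20 | ~100 non-homologous decoys at n=500 |
| nanochromosome length | lognormal, median 2 kb, σ=0.45 | gene-sized chromosome scale |
| telomere caps | 2–7 units C4A4/G4T4, dropout 0 | fully capped by default; dropout exercises QC |
| FPKM | lognormal, mean 10.59 (PRF) / 44.38 (normal), σ=1 | frameshifted genes lowly expressed |

Proteins are drawn by sampling *sense codons* at the coding GC target and
translating — this yields the AT-biased amino-acid composition such a genome
really has, so reverse-translated transcripts meet the same GC target
(realized coding GC is within ~1.5 points of target; the conditional
exclusion of AT-rich stop codons shifts it slightly upward).

For a planted frameshift, the +1 overlap arithmetic fixes two protein
residues: the P-site codon encodes the residue before the shift, and the
post-shift codon — stop[2:3] + next nucleotide, e.g. AAA for UAA-A — encodes
the residue after it.  The generator sets those two residues of the source
protein accordingly (as in real +1 PRF genes, where the junction carries
Lys) and then guarantees, re-checked on every build: the planted stop is the
first in-frame stop after the upstream segment, deleting its T yields a
junction ORF translating exactly to the source protein, and no chance
GT..AG of length ≡ 1 (mod 3) sits near the junction (rejection sampling) —
so the decoy and signal classes are separable by construction.
Intron-retention decoys insert a GT..AG segment of length ≡ 2 (mod 3)
(26–122 nt) at a codon boundary; non-homologous decoys are random noncoding
sequence.  One source protein per transcript; decoy transcripts leave their
protein in the search set as a distractor.

All randomness flows from one numpy PCG64 stream in a fixed draw order
(proteins → transcripts → nanochromosomes → FPKM); any change to the draw
order is a breaking change to fixtures.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequencing error and coverage variation; paralogy
and multi-domain proteins (a knob exists for one protein per transcript
only); diverged rather than exact homology (planted segments are identical
to their source, so recovery rates here are upper bounds); genuine splice
variation beyond the single retained-intron decoy; chimeric assemblies; and
any RNA secondary-structure context of the shift site.

## Numerical and operational choices

* Scores are int32 throughout the aligner; the masking sentinel scores −10⁶
  so masked residues can never participate.
* Traceback tie-breaks are fixed (diagonal, then subject-gap, then
  query-gap), making hit coordinates deterministic.
* Fisher p is normalized by the summed pmf so the all-tables-qualify case
  returns exactly 1.0 despite float summation.
* Degenerate inputs: empty margins give p = 1; zero-variance equal-mean
  expression groups give t = 0, p = 1; contigs shorter than the telomere
  motif classify as 0-telomere with a warning; a transcript that fails in
  the pipeline is logged and skipped, never fatal.
* Data files never contain timestamps; JSON is written with sorted keys —
  reruns are byte-identical and diffable.

## Problem sizes

The default benchmark (500 transcripts, ~55 planted sites, ~500 proteins)
runs the full pipeline in a few minutes on one CPU; unit tests use an
80-transcript dataset.  The exhaustive Fisher sweep covers all 164,175
2×2 tables with margins ≤ 30.  These sizes were chosen to make the complete
analysis reproducible on a laptop; the statistics scale with n, and the
Fisher test on stop-codon usage in particular is underpowered at ~55
slippery stops (p ≈ 0.1–0.4 for the configured skew) — the skew itself is
reproduced, and the test's p-value shrinks monotonically with n, which is
asserted as a property.

## Known limitations

* The E-value calibration is approximate (ungapped parameters on gapped
  scores); absolute E-values should not be compared with NCBI BLAST output,
  though rankings agree.
* The intron heuristic models canonical GT..AG introns only, and cannot
  distinguish a retained intron from a frameshift when the intron length is
  within ~15 nt of the frameshift explanation.
* Minus-strand handling analyzes the reverse complement when a reverse
  orientation scores best; site coordinates of such calls refer to the
  reverse complement, which is noted in the call record.
* Slippery stops are required near the homology junction; frameshifts not
  mediated by a 0-frame stop, and −1 events, are out of scope by design.
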