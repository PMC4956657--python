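# Methods

This note documents the models, parameter choices and numerical decisions
behind each pipeline stage, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Read preprocessing

Cleaning order is quality → 5′ primer contaminant → 3′ adapter trim →
poly-A → N → length.  "Low quality" is operationalised as mean Phred < 20
when qualities are present (the filter is named in the field's pipelines
but rarely given a threshold); the poly-A rule is ≥ 80 % A after trimming;
adapter trimming is a leftmost 3′ prefix search allowing one mismatch per
10 nt of overlap (minimum overlap 5 nt).  All knobs live in
`PreprocessConfig`.  Every filter is conservative: reads in = reads kept +
itemised removals, asserted in the pipeline.  The 18–30 nt gate is
inclusive on both ends.

Collapsing maps the clean-read multiset to unique tags with per-library
counts; tag ids are ordinals in (descending count, sequence) order so that
identical inputs give identical files.

## Annotation and families

Matching is ungapped Hamming distance of the whole tag against every
equal-length reference window — the gapless mismatch mode of the short-read
aligners used for this kind of data — with ≤ 2 mismatches by default for
both the structural-ncRNA subtraction and known-mature identification
(independently configurable, since the two bounds are stated separately in
the protocols this follows).  Genome/transcript sets are searched on both
strands, mature/precursor/ncRNA sets forward-only.  Ties break by fewest
mismatches, then lexicographically smallest reference id.  The matcher is
vectorised (per-length window matrices) and verified against an exhaustive
scan in the tests.

Category priority is rRNA > tRNA > snRNA > snoRNA > miRNA > unannotated,
which reproduces the subtract-ncRNA-first convention; the ncRNA subtype is
read from the reference id (an untyped ncRNA defaults to rRNA, the top
category).  Families merge by a curated alias table shipped as editable TSV
(`miR156/157`, `miR165/166`); the fallback rule strips species prefixes and
letter/arm suffixes.  The family WA/WB ratio is computed on raw read counts
(not RPM), which is what reproduces the published family-table ratios
(1.35, 2.04, 1028.09) exactly; a zero denominator renders as "–".

## Hairpin discovery

Only unannotated tags with ≥ `min_reads` (default 5) total reads and a
20–24 nt length are considered — an abundance prescreen standard in
hairpin-prediction tools, without which every singleton background tag
would be folded.  Tags must map perfectly (0 mismatches) to ≤ 15 loci.
Per locus two windows are excised, biasing the tag toward either arm
(20 nt upstream / 160 nt downstream and the mirror), clipped at reference
bounds; minus-strand loci are reverse-complemented so the mature always
sits on the precursor strand.

Folding is pluggable.  The default (`fold_backend="auto"`) uses the
thermodynamic ViennaRNA MFE fold when the `RNA` bindings are importable —
publication-grade energies and far cleaner hairpins on random flanking
sequence — and otherwise the built-in folder: an exact dynamic programme
maximising pair scores GC=3, AU=2, GU=1 plus a +1 bonus per stacked
adjacent pair, minimum loop 3, with a deterministic traceback (pair >
left-unpaired > right-unpaired > smallest split).  The built-in score is
reported as a negated pseudo-energy and flagged `pseudo`; the |MFE| ≥ 18
kcal/mol gate applies only under the thermodynamic model, where the unit is
meaningful.

Screening instantiates the community criteria for plant miRNA annotation:
mature entirely on one arm of the loop; ≤ 4 duplex mismatches (unpaired
mature bases); ≤ 2 nt asymmetric bulge (register differences between
consecutive paired mature bases); ≥ 60 % of mature bases paired.  The star
is derived from the fold's pair table — the duplex partner of the mature
with the canonical 2-nt 3′ overhang, projected through the nearest paired
base where ends are unpaired — and flagged "observed" when that exact
sequence occurs among the sequenced tags.  Candidates are deduplicated by
locus: a tag whose genomic footprint falls inside an accepted precursor
(e.g. the star strand) is the same hairpin.  Names are `miRn1..k` ordinals
in discovery order (descending abundance).

Planted-truth behaviour: substitutions planted in the star arm may still
pair as G:U wobbles (reported mismatches undershoot by 1) or destabilise a
neighbouring pair under the thermodynamic model (overshoot ≤ 2); the tests
encode exactly this envelope.  A planted 2-mismatch arm occasionally folds
with a > 2 nt bulge and is then correctly rejected — recall on planted
hairpins is therefore high but not 100 % unless the arms are perfect
complements.

## Differential expression

Normalisation divides by the library's **total clean reads** (not the
miRNA-only total) × 10⁶.  This choice is validated by the worked example:
443 reads against 20,287,225, with the 0.01 pseudo-expression substituted
for the zero count in the other library, reproduces the published 11.09
log2 fold change exactly; a miRNA-total denominator does not.  The pseudo
is applied on the normalised scale, as specified, not to raw counts.

Significance is the two-sided Audic–Claverie test.  The conditional law of
the second count given the first is negative binomial with r = x+1 and
success probability 1/(1+t), t = n₂/n₁; both tails are evaluated through
the regularised incomplete beta function (the exact NB tail identity),
which is stable to ~1e-300 — the far tails needed at these library depths.
The doubled smaller tail is capped at 1.  The test conditions on the first
library's count, so exchanging library labels changes p only within a
bounded factor (quasi-symmetry) while fold changes negate exactly; the
tests assert precisely this.  Fisher's exact test on the 2×2 table is the
pluggable alternative.  Calls use raw p ≤ 0.05 and |log2FC| ≥ 1 — the
fold-change threshold is read on the log2 scale, since that is the scale on
which the fold change itself is defined.  BH q-values are reported but
never affect calls.  Counts that are zero in exactly one library get a
`WA-only`/`WB-only` flag.

## Target prediction and network

The expectation score follows the classic plant scheme: per aligned
position, mismatch 1.0, G:U wobble 0.5, indel 2.0, doubled at miRNA
positions 2–13 (the 5′ seed); at most one indel; sites qualify at
expectation ≤ 3.0.  For unequal lengths the minimum over single-gap
placements is taken (ties to the 5′-most gap); the transcript scan uses an
exact branch-and-bound shortcut — an alignment whose running total exceeds
the cutoff can never yield a hit, and a gap inside the seed costs 4 on its
own, so those placements are skipped when the cutoff is below 4.
Overlapping sites keep the lowest expectation; output order is
(expectation, transcript, position).  Inhibition is "translation" when any
penalty falls at positions 9–11, else "cleavage".  The network keeps edges
for DE miRNAs only; negative correlation is recorded when a supplied target
expression direction opposes the miRNA's call.  Dangling miRNA ids are
skipped and counted, never fatal.

## Synthetic study

The generator emulates the study design: two libraries (WA/WB) of
200,000 reads each (18–30 nt), 30 known matures, 20 novel hairpin loci
planted in a 100 kb genome, 10 structural-ncRNA decoys (~20 % of reads),
and background reads sampled from both genome strands.  Per-miRNA WA
counts are Poisson(mean) with means log-uniform on [50, 2000]; WB counts
are Poisson(mean·2^−fc).  By default 60 % of miRNAs are unchanged and the
rest draw fc from {±1, ±2, ±3}; ±∞ encodes library-specific miRNAs.  Star
reads are sampled at 5 % of the mature rate from the exact canonical star
sequence; substitution noise is 0.001/base.  Poisson rather than negative
binomial because the emulated design pools stages into one library per
condition — no overdispersion is estimable.  Planted hairpins are
mature + loop(8–15 nt) + near-reverse-complement arm (≤ 2 substitutions
away from the ends) + a 2 nt tail so the canonical star lies inside the
cassette; loci are spaced > 250 nt so excision windows never merge
adjacent loci.  Transcripts (25 × 300 nt) carry planted perfect-complement
sites for about half the miRNAs.

What it does **not** emulate: adapter ligation and its biases, low-quality
tails, sequencing-error profiles beyond uniform substitutions, expression
correlation between family members, and real transcriptome complexity.
Passing the recovery tests therefore demonstrates the correctness of the
pipeline's logic under the stated generative model, not performance on real
libraries.

## Problem sizes and determinism

The bundled analysis and the acceptance script run the full default
conditions (two × 200,000 reads, 100 kb genome) in a few minutes on one
core; unit tests use smaller instances of the same generator.  All
randomness flows from a single integer seed through
`numpy.random.default_rng`; identical config + seed gives byte-identical
report tables.  The run log records versions, seeds and per-stage read
accounting.

## Limitations

* One library per condition: no replicate-aware inference (negative
  binomial GLMs are out of scope by design).
* ncRNA subtraction is by sequence match against supplied references, not
  covariance-model scanning.
* The genome-scale published catalogs (162 known miRNAs, 27 novel
  families, 489 targets) depend on unavailable raw libraries and reference
  sets and are reproduced structurally on synthetic data, not numerically;
  published precursor MFEs depend on a specific folding parameter set and
  are not asserted.
* Novel miRNAs with identical mature sequences collapse by construction
  (one candidate per tag, deduplicated by locus; a multi-locus tag reports
  its first accepted locus).  No looser variant clustering into "novel
  families" is attempted, since no published rule defines it.
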