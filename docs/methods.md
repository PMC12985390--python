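# Methods

This note records the models implemented in `cfends`, the defaults and why,
the numerical choices, and what the synthetic data do and do not emulate.

## Coordinates, strands, and motif definitions

All coordinates are 0-based half-open (BED convention); loaders accept
1-based input behind an explicit flag. A fragment's strand is the
orientation of the sequenced single-stranded molecule, and every motif is
reported 5'→3' in that molecule's frame: for a "−" fragment the four motifs
are computed on the reverse complement of the locus, so its "upstream"
flank (PREM) lies at higher genomic coordinates. Motifs that would overlap
a contig boundary, fall inside a fragment shorter than k, or contain N are
*unavailable* and excluded from both the numerator and the denominator of
spectrum frequencies, keeping Σ F_i = 1 over the 4^k motif domain. Each
motif class is normalized independently.

Alignment-level filters default to the short-read regime — insert size
20–600 bp inclusive on both ends, at most 2 mismatches — with mapQ ≥ 30
available for the duplex/long-read regime. Filters on absent columns are
skipped and logged. Duplicate fragments are not collapsed.

## Expected frequencies and the sonicated correction

Expected genome frequencies slide a step-1 k-window over **both strands** of
every contig (fragment ends arise on both strands), skipping N windows. The
sonicated-DNA correction is
`corr_i ∝ F_i(plasma) / F_i(sonicated) × Expected_i`, computed motif-wise
with a pseudocount of 0.5 added to sonicated counts (division-by-zero
guard) and the corrected vector renormalized to sum to 1. The correction
removes *pre-analytical* (library/protocol) end bias: it cancels exactly
those multiplicative biases that plasma and the sonicated control share,
and reduces to the identity when the sonicated spectrum equals the expected
one. The simulator therefore distinguishes biological cut bias (plasma
only) from protocol bias (applied to plasma *and* sonicated); only the
latter is correctable by construction. Correction is an optional stage, off
by default.

## Differential motifs and EMR

Per-motif group comparison uses the two-sided Wilcoxon rank-sum test on
per-sample frequencies — exact when both groups have n ≤ 10 and no
cross-group ties, otherwise the normal approximation with continuity
correction, ties mid-ranked; identical groups short-circuit to p = 1.
Benjamini–Hochberg adjustment is applied within one motif class (256 tests
at k = 4). Fold change is the ratio of group medians, with a
pseudo-frequency of 1/(2·median n_ends) substituted for a zero median.
Ranking uses the relative percentage change of medians; motifs with a zero
control median are excluded from ranking. Z scores for heatmaps use the
sample SD (n−1) — appropriate for small cohorts — with zero-variance rows
set to 0. The EMR is a per-sample scalar, Σ F(increased)/Σ F(decreased)
over disjoint, nonempty motif sets (by default the differential sets from
the case-vs-control screen); a zero denominator yields an explicit
undefined flag rather than infinity.

## FRAGMA

The cleavage proportion at site *i* is 100 × (fragment ends at *i*) /
(fragments covering *i*), where an end "at *i*" means the 5' (or 3')
*terminal base* occupies *i* in the molecule's own orientation. Profiles
use an 11-position window anchored at the Watson C of the CpG (position 0);
the ±5 nt window leaves the anchor base a convention choice, and the C is
recorded in output metadata. Crick-strand fragments are merged 5'→3' via
the symmetric frame (anchor = the G at pos+1, orientation flipped), so a
genome-wide reverse complement of the experiment leaves profiles invariant
(tested). Per-site proportions are averaged **unweighted** across CpGs,
which is robust to coverage heterogeneity; pooled-count averaging is
available by flag. Sites below a minimum depth (default 1) are excluded
from the mean.

CpG classes follow the density rules: tissue-wide hyper >70% in all
configured tissues, hypo <30% in all; tumor-specific hyper = tumor >70% and
buffy coat <30% (hypo mirrored). Tumor-specific labels take precedence when
both apply. The FRAGMA feature vector concatenates the four class profiles
(category, then position ascending): 44 features per end type.

## Duplex (4-end) model

A duplex molecule is the pair of intervals of its Watson and Crick strands;
"size" is the Watson-strand length (matching single-strand conventions;
the outer span is available). End geometry follows from the interval
offsets — at the left side, Watson starting first is a 5' overhang, Crick
starting first a 3' overhang — and the adapter pool covers blunt plus both
overhang kinds at lengths 1–20 (41 adapters). Barcodes are a deterministic
greedy lexicographic 6-mer code with pairwise Hamming distance ≥ 3:
distance 2 would *not* make single-substitution rescue unambiguous (a
corrupted word can lie at distance 1 from two codewords at mutual distance
2), so the stronger code is generated; one-mismatch rescue is enabled by
default and ambiguous or distant barcodes are rejected with a count.
The shipped barcodes are synthetic functional equivalents; no published
oligo sequences are reproduced. Overhangs beyond 20 nt are unligatable and
dropped, emulating exonuclease loss of open products. `decode ∘ encode` is
the identity on all modalities (tested on 10^4 random molecules).

The 4-end motif `a→b d←c` places the Watson strand 5'→3' in the numerator
and displays the Crick strand antiparallel (3' end first); Watson
orientation is fixed by the reference. Spectra cover the full
4^(a+b+c+d) space. Nuclease attribution looks up, on one side of the
molecule, the 5' dinucleotide of one strand and the 3' dinucleotide of the
complementary strand in the shipped signature sets (DNASE1L3: 5' GG / 3'
CT; DNASE1: 5' CT / 3' CG; DFFB: 5' {AC,AT,AA,AG,GA} / 3'
{GC,GT,AG,GG,TC}); pairs are unordered (6 labels), and motifs matching no
or several nucleases are unassigned. Signature abundance is
observed/expected per size bin, with expected frequencies from molecules
redrawn uniformly at 10× the observed count while preserving each
molecule's (size, jagged-offset) geometry, seed-fixed to bound Monte-Carlo
error. Default bins [20,130), [130,200), [200,400), [400,600), [600,1000)
bp encode the commonly named 130/200/600 bp landmarks.

## Classification harness

Features concatenate per-class, per-stratum spectra in deterministic order
(class, stratum, motif alphabetical); the default 4 × 256 × 3 = 3,072
columns. The classifier is a linear-kernel SVM with C = 1 (kernel and
hyperparameters are otherwise unconstrained choices) under leave-one-out
cross-validation; standardization and Platt probability calibration are
fitted on each training fold only, so no held-out sample influences its own
preprocessing — the leakage-safe reading of an ambiguous protocol
description. AUC is the Mann–Whitney statistic with ties counted 0.5
(verified against exhaustive pair counting); sensitivity at a specificity
threshold is the highest sensitivity among operating points meeting it.
DeLong's paired test is implemented with the fast midrank algorithm (no
installed package provides it) and cross-checked against a paired
bootstrap. Bootstrap CIs resample within class (stratified) to avoid
single-class resamples. Downsampling draws fragments without replacement
per sample at each grid level and re-runs the whole pipeline.

**Known estimator property.** Leave-one-out AUC is pessimistically biased
when the feature dimension far exceeds the sample count: with 3,072
features and 20 samples per group, the permuted-label mean AUC measures
≈0.36–0.40 rather than 0.50, and no monotone per-fold transform (C, class
weights, score centering) changes it, because out-of-fold scores from
different folds are not exchangeable in the p ≫ n regime. This deflation is
the opposite of leakage (which inflates); the harness's null calibration is
therefore validated at p < n (16 dinucleotide features), where the
estimator is near-unbiased, while discrimination claims use the full
matrix. Interpret near-chance LOOCV AUCs on very small, very wide cohorts
with this bias in mind.

## Synthetic data

The generator emulates, at desk scale, the statistical structure the
analyses assume; all randomness flows from one seed and outputs are
byte-identical under a fixed seed.

* **Reference**: i.i.d. bases at a configurable GC fraction (default 0.42),
  one contig; default test/acceptance length 120–200 kb.
* **Sizes**: a two-component normal mixture with means 52 and 166 nt
  (SDs 9 and 22, weights 0.30/0.70) truncated to the 20–600 nt retention
  window, with a cosine comb of period 10 nt and amplitude 0.2 on the short
  component — the periodicity is reported as weak, so the default amplitude
  is mild.
* **Cut placement**: rejection sampling; a candidate fragment is accepted
  in proportion to the product of 4-mer context weights at its two ends
  (5'-side weight keyed on the upstream/PREM frame, 3'-side on the
  downstream/POEM frame, per strand). Exactness over speed at desk scale.
* **Case effects**: a per-stratum size re-weighting (defaults 0.75 / 1.05 /
  0.90 for short / mononucleosomal / long — fewer short fragments, slight
  mid-range gain, long-fragment loss) and multiplicative 5'-context motif
  shifts (defaults: A/T-rich contexts up ×1.5–1.8, CG-rich down ×0.5–0.6,
  echoing the direction of liver-cancer plasma shifts). Absolute effect
  magnitudes are not derivable from published summary statistics; defaults
  are chosen for testability and labelled as such.
* **Methylation anchoring**: a fraction of fragments (default 0.12) is
  re-anchored at hypermethylated CpGs with the 5' terminal base at offset 0
  or the 3' terminal base at offset −1 (strand-symmetric frames); cases
  boost tumor-specific hyper sites ×2 by default.
* **Duplexes**: per-side nuclease choice from size-dependent activity
  tables (defaults emulate DNASE1-dominated short, DNASE1L3-dominated
  mid-range, and DFFB-enriched >600 bp regimes); a constrained side places
  its cuts at signature-matching dinucleotide contexts, with Crick offsets
  drawn from a blunt/5'/3' mixture (0.25/0.35/0.40, truncated-geometric
  lengths 1–20). The conditioning mechanism is a modeling choice: real
  signatures were *defined* from knockout contrasts, and only the
  observed/expected measurement is specified, so the generator realizes
  activity by constrained placement.
* **Sonicated control**: uniform cut positions (motif-blind biologically),
  sharing the size mixture and any configured protocol bias.

Problem sizes in the shipped tests and acceptance script (cohorts of up to
2 × 20 samples × 6,000–40,000 fragments on a 120 kb genome) are the
package's choice of desk-scale defaults; the generator accepts larger
values. What passing tests show is that the *operations* recover the
structure the generator injects; real plasma adds features the simulator
does not model — sequencing error, PCR/UMI duplication, nucleosome-phased
cut maps, chromosomal copy-number structure, tissue-of-origin mixtures —
so performance numbers on synthetic cohorts are properties of the harness,
not clinical estimates.

## Degenerate inputs and tie-breaks

Zero usable ends yield an n_ends = 0 spectrum with NaN frequencies and a
warning; empty CpG categories and single-class cohorts raise errors naming
the offender; depth-0 sites are excluded rather than scored; all-tie score
vectors give AUC 0.5; an EMR with a zero denominator is flagged undefined.
Size strata are half-open with 166 nt assigned to the third stratum, and
the 601 upper bound encodes the inclusive 600 nt retention filter.
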