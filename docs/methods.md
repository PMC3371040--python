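# Methods

This note documents the statistical procedures implemented in
`postvar`, the assumptions behind them, the tunable parameters with
their defaults, what the synthetic-data generators do and do not
emulate, and the design choices made where the design was genuinely
open.

## Evaluation against a validation truth set

The unit of evaluation is a *truth entry*: a variant key
`(chrom, pos, ref, alt, sample)` with a binary outcome from an
orthogonal assay (`validated` / `failed`).  The evaluation universe is
the truth set itself — variants never submitted for validation carry no
information and are ignored.  Under a cutoff pair `(qual_min, dp_min)` a
truth variant is *predicted* when it is present in the call set with
`QUAL ≥ qual_min` and `DP ≥ dp_min` (cutoffs inclusive).  This yields

* TP — predicted and validated,
* FP — predicted but failed,
* FN — not predicted (including absent from the call set) but validated,
* TN — not predicted and failed,

which always sum to the truth-set size.  Derived metrics:
`recall = TP/(TP+FN)`, `accuracy = TP/(TP+FP)` (i.e. precision — the
name matches the validation-study convention the toolkit follows),
`F = 2·TP/(2·TP+FP+FN)`, and the cutoff-independent
`validate_rate = (TP+FN)/total`.  A metric with a zero denominator is
*undefined* and carried as such (`None`), never silently zero; undefined
F scores are excluded from maximization.  Percentages in reports are
rendered with two decimals, round-half-up; F scores with four decimals.

DP is taken from `INFO:DP` (the caller's raw site depth), not from the
sum of `DP4`, which counts only the high-quality subset.  Records
lacking `DP` cannot satisfy a positive depth cutoff and are excluded
from depth-based operations with a logged warning.

### Cutoff grid search

The grid is exhaustive: every integer pair in QUAL 15–35 × DP 3–15
(defaults; both ranges configurable) is evaluated and all pairs
attaining the maximal defined F score are reported.  Ties are not
broken — on small validation sets entire plateaus of cutoffs are
typically optimal, and reporting the full set is more informative than
an arbitrary representative.  Maximization uses unrounded F values;
rounding happens only at the reporting layer.

### Depth-bound pre-filter and concordance

`apply_filter` reproduces the classic varFilter-style depth window
(defaults `3 ≤ DP ≤ 10000`, plus an optional QUAL floor), preserving
input order.  `qual_concordance` matches two call sets on variant key
and reports the sample Pearson correlation of QUAL pairs together with
the fraction of pairs in which the first set scores strictly higher;
fewer than two matched pairs, or zero variance, is an error rather than
a NaN.

## Allele/strand balance

For each variant the `DP4` field gives high-quality read counts
(ref-forward, ref-reverse, alt-forward, alt-reverse).  The indicator
`lacks_support` is 1 iff any component is below the support threshold
(default 1 read — "no support in at least one of the four classes").
The indicator is cross-tabulated against validation status:

|                | validated | failed |
|----------------|-----------|--------|
| lacks support  | a         | b      |
| full support   | c         | d      |

and association is tested with a two-sided Fisher's exact test
conditioning on both margins: the p-value sums the hypergeometric
probabilities of all tables with the observed margins whose probability
does not exceed that of the observed table.  The implementation
enumerates the support of the free cell with exact integer binomial
coefficients (`math.comb`); since all probabilities share the
denominator `C(n, a+c)`, tie comparison is performed on integer
numerators and is exact — no floating-point tie tolerance is needed, and
the observed table is always included, so `p ≥ P(observed) > 0`.  A zero
row or column margin returns `p = 1` by convention (no association is
testable).  Sidedness: two-sided by default; the classical conditional
test without mid-p correction.

The indicator is reported as a diagnostic, not applied as a hard filter
by default: requiring support in all four classes typically does not
improve recall or accuracy even when the association with validation
failure is strong, because the deficient variants largely coincide with
those already removed by QUAL/DP cutoffs.

## Spurious-exon detection

Reads originating from a genomic region absent from the reference can
be forced, with mismatches, onto a homologous region that is present,
producing recurrent artifactual variant calls there.  The signature is
local: inflated coverage and low mapping confidence over a whole exon,
not just one site.  The exon is therefore the analysis unit.

For each sample, a read (mapped, primary, non-duplicate, MAPQ ≠ 255)
counts toward every exon its reference span overlaps by at least one
base (0-based half-open arithmetic; a read overlapping two exons counts
in both).  Then

* `RPE_e = (count_e / length_e) / (R / L)` where `R` is the sample's
  total exonic read count and `L` the total exon length — the exon's
  read density relative to the sample's mean exonic density.  This form
  makes `RPE ≈ 1` for an average exon, makes the flagging threshold
  `RPE > 1.5` interpretable as "50% above average density", makes the
  same exon comparable across samples with different yields, and obeys
  the identity `Σ_e RPE_e · length_e = L` exactly.  The denominator
  choice (density ratio rather than raw read-count ratio) is a design
  decision; it is the only normalization under which a single fixed
  threshold is meaningful across exons of different lengths.
* `P_HQR_e` = fraction of the exon's reads with `MAPQ ≥ 40`
  (threshold configurable).  MAPQ is
  `round(−10·log₁₀ Pr(mapping position is wrong))`, capped at 60; 40
  corresponds to a 1-in-10,000 error probability and separates the
  confident-unique mode near 60 from the ambiguous-mapping mass below.
  An exon with zero reads has undefined `P_HQR` and is never flagged.

An exon is *flagged* iff `RPE > 1.5` **and** `P_HQR < 0.4` (both
strict, both configurable; the values are deliberately conservative
markers of the outlying quadrant, not estimated decision boundaries).
Across a cohort — matched controls included, since the artifact is
platform/reference-driven, not disease-driven — exons are ranked by the
number of distinct samples in which they are flagged, and reported when
that count reaches `min_samples` (default 31, i.e. "more than 30"
samples of a 36-sample cohort).  The module detects the mismapping
signature; locating the homologous source region is out of scope.

## Synthetic fixtures

The generators are pure functions of their parameters: a fixed seed
yields byte-identical files (plain-text VCF/SAM emission, stable
formatting).

**Variant sets.**  Two classes, true (`validated`) and false
(`failed`).  Default composition 65 true / 94 false mirrors a validated
exome SNV call set of 159 candidates (the indel preset uses 12/10).
QUAL is normal per class, truncated at zero (defaults: true
45 ± 8, false 16 ± 6), DP negative-binomial (true mean 30, false mean
8, dispersion 8 and 4), chosen to reproduce the overlapping-but-shifted
scatter validation studies observe.  Both depth floors default to 4:
fewer than four reads cannot populate all four allele/strand classes,
and the depth-bound pre-filter removes ultra-shallow sites in this
workflow anyway.  `DP4` splits a high-quality subset (binomial, 90% of
DP) between alleles and strands with one read guaranteed per class,
then, with per-class probability (`0.05` true / `0.8` false), zeroes one
uniformly chosen component — so the lacks-support indicator is exactly
Bernoulli per class, the simplest mechanism producing the observed
enrichment of strand deficiency among failed variants.  The
`planted_separation` preset instead truncates QUAL into disjoint class
ranges ([30, 60] vs [0, 25]) with true-class DP ≥ 6, so a perfect
cutoff exists by construction and grid-search recovery can be asserted
exactly.

**Alignment sets.**  A cohort of single-end, gap-free 100-base reads on
the exons of one synthetic contig.  Non-spurious exons draw
Poisson(0.5 reads/base × length) reads (≈50× depth, typical of captured
exomes) with 5% low-MAPQ reads; planted spurious exons draw 3× that
density with 80% low-MAPQ reads.  Low MAPQ is uniform on [0, 39], high
on [45, 60].  Per-sample streams are seeded independently from
`(seed, sample_index)`.

What the fixtures do **not** emulate: real base sequences or error
profiles, paired-end structure, indel-containing CIGARs, GC or capture
bias, correlated mapping errors between neighboring exons, or label
noise in the truth set.  Consequently, passing recovery tests shows the
statistics and decision rules are implemented correctly and are
sensitive at realistic effect sizes; it does not certify performance on
real cohorts, where class separations are weaker and validation
outcomes can themselves be wrong.

## Numerical and interface choices

* Coordinates: BED 0-based half-open, VCF/SAM 1-based; all internal
  interval logic 0-based half-open.
* Multi-allelic VCF records are split per ALT (QUAL/DP/DP4 duplicated)
  with a warning; `sum(DP4) > DP` is rejected with a named error.
* Undefined metrics propagate as `None` end to end and render as `NA`.
* Grid ties: all maximizers reported; downstream consumers choose.
* Fisher: exact integer arithmetic, hence deterministic and
  tolerance-free; cross-checked in the test suite against an
  independently coded exact-fraction enumeration and against
  `scipy.stats.fisher_exact`.
* Problem sizes in the test and acceptance runs (200-variant planted
  sets, 36-sample × 10-exon cohorts at 50×, five cohort seeds, Fisher
  enumeration to table total 40) were chosen as the smallest sizes at
  which every claimed recovery is structurally guaranteed rather than
  borderline, keeping the full suite fast enough to run routinely.
* Reports are TSV with a reproducibility header (version, config hash,
  seed); identical configuration reproduces byte-identical reports.
  VCF output preserves validity and appends a filter-provenance header
  line.

## Known limitations

* The truth-set evaluation conditions on the validated subset; it
  cannot estimate genome-wide false-negative rates.
* ROC/AUC analysis is deliberately absent: with validation performed
  only on a selected candidate subset, score-threshold sweeps over the
  full call set are not estimable.
* The spurious-exon quadrant thresholds are conservative conventions,
  not fitted decision boundaries; cohorts with very uneven capture
  efficiency may need them re-tuned.
* The per-variant strand diagnostic is binary; no phred-scaled
  strand-bias score is computed.
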