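# Methods

This note documents the statistical procedures implemented in `metapair`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data tests do and do not demonstrate.

## Study design being modeled

A matched case-control design: patients who develop left-ventricular
remodeling (LVR) after STEMI are paired one-to-one with non-remodeling
patients matched on clinical variables (age, sex, ejection fraction,
infarct size, culprit artery, time to reperfusion). The default
configuration has 32 pairs (64 subjects). Serum is profiled on a targeted
kit quantifying up to 188 metabolites across 6 biochemical families
(acylcarnitines including free carnitine, amino acids, biogenic amines,
lysophosphatidylcholines, phosphatidylcholines, sphingomyelins, and the
hexose sum), in µmol/L, each with a lower and upper limit of quantitation
(LLOQ/ULOQ). Routine biomarkers (CK, CK peak, hs-cTnI, CRP, leukocyte and
neutrophil counts, NT-proBNP, creatinine) accompany the panel.

## Quantitation filter

A cell is out of range iff its value is strictly below LLOQ or strictly
above ULOQ; values exactly at a limit are quantified. Missing cells count
as out of range. A metabolite is dropped when **more than** 20% of its
values are out of range — the threshold is strict, so exactly 20% keeps
the metabolite (13 of 64 flagged drops; 12 of 64 keeps). Under the default
synthetic panel this retains 142 of 188 metabolites (75.5%) with the family
breakdown 12 + 21 + 12 + 12 + 70 + 14 + 1. Flags, not values, drive the
filter: out-of-range cells keep their numeric value, as kit exports do.
The filter is idempotent and per-metabolite (column-order invariant).

## Univariate testing

Normality is assessed per variable with Shapiro–Wilk at α = 0.05: on the
within-pair differences for paired comparisons, per group for unpaired
comparisons (both groups must pass). The parametric branch uses the paired
*t*-test or, unpaired, Welch's *t* (a flag restores pooled variance — the
pooled form is a stricter reading of "Student's test" but Welch is the
safer default under unequal variances). The nonparametric branch uses the
Wilcoxon signed-rank test (exact null up to 25 non-zero untied
differences, normal approximation with continuity and tie correction
above; all-zero differences return p = 1) or the Mann–Whitney test.
Constant input makes Shapiro–Wilk undefined; the nonparametric branch is
taken with a warning.

All variables passed to one `compare_groups` call form a single
Benjamini–Hochberg family (step-up, adjusted p capped at 1, monotone in
ranks); biomarkers and metabolites are adjusted as separate families by
being analyzed in separate calls. The family composition is configurable
because with small families the step-up boundary can flip individual
verdicts, and reasonable analysts draw the family differently.

## Multilevel (paired) latent-variable models

"Paired" PCA and PLS-DA are implemented as the multilevel within-pair
deviation transform followed by the standard algorithm: each sample is
replaced by its deviation from its pair mean (for two-member pairs,
±(case − control)/2, computed antisymmetrically so pair sums are exactly
zero). The transform is pair-local, so applying it before train/test
splitting leaks nothing across pairs. A flag disables it for ordinary
(unpaired) PCA/PLS-DA, since pair-respecting partitioning alone is the
other defensible reading of a "paired" multivariate analysis.

Unit-variance scaling (mean 0, sd 1, n−1 denominator) is fit on the
training partition and re-applied — never refit — to test samples;
zero-variance training columns are dropped with a warning. A flag-free
whole-matrix scaling variant is deliberately *not* offered inside the
engine, as it leaks test information into training.

PCA and PLS components are extracted by NIPALS with tolerance 1e−12 and a
20,000-iteration cap (power iteration converges linearly at the ratio of
consecutive eigenvalues; a few hundred iterations are not enough at this
tolerance when the spectrum is flat). The sign convention makes the
largest-magnitude loading element positive. For a single response, PLS1
weights are closed-form per component (w ∝ Xᵀy). Hotelling's T² per
sample is Σₐ t²ₐ/var(tₐ) with the control limit A(n−1)/(n−A) · F₍α₎(A, n−A)
at α = 0.95 by default. VIP scores use the explained-response sum of
squares per component as weights; mean(VIP²) = 1 identically, so VIP > 1
marks above-average contribution.

## Partition validation engine

Partitions operate at **pair level**: both members of a pair are assigned
together, 22 pairs (44 samples) to training and 10 pairs (20 samples) to
testing, giving C(32,22) = 64,512,240 possible splits — this pair-level
count is what makes the combinatorics match the study design. Splits are
indexed by lexicographic rank and materialized on demand by combinadic
unranking (O(k) per split, O(1) memory); the systematic sample takes every
310th rank from offset 0 (both configurable), 208,104 models in the
default design. Each model is fit on the scaled training block with 2 PLS
components (configurable; 2 is the usual choice for score-plot-driven
metabolomics workflows), scored on the test block, and summarized by the
rank-based AUROC.

### The AUROC null and its calibration

The per-model p-value asks: how extreme is this AUROC if the classifier
were the "mean model", predicting status at random? Two reference nulls
are implemented:

- **Mann–Whitney null** (`auroc_pvalue`): the classic U distribution for
  independent samples — exact via dynamic programming when
  n₊·n₋ ≤ 400, else a continuity-corrected normal approximation.
- **Mirrored-pair null** (`paired_auroc_pvalue`, engine default): after
  the within-pair transform, a linear model scores the two members of a
  test pair as exact mirror images, c ± eᵢ. The concordance count becomes
  U = #{(i,j): eᵢ + eⱼ > 0}, and by the Walsh-average identity with the
  signed-rank statistic, U = Σᵢ (2i−1)·Bᵢ with Bᵢ iid fair Bernoulli given
  exchangeable labels — an exact, distribution-free null.

The distinction matters: simulations over replicate no-signal cohorts show
the Mann–Whitney null rejects ~17% of paired-transformed models at the
nominal 10% (the mirror symmetry roughly doubles Var(U)), while the
mirrored-pair null is exactly calibrated. Without the pair transform the
Mann–Whitney null is conservative on matched data (pair correlation shrinks
Var(U)). The engine therefore pairs each transform with its matching null
by default.

Significance per model uses the **directional** (undoubled,
observed-direction) tail probability. This is the convention under which
the mean-model argument comes out right: ~5% of null models are
significantly better than chance and ~5% significantly worse, ~10%
combined — and it is what the engine's `fraction_significantly_better/
worse` report separately so the two tails can be audited rather than
conflated. The doubled two-sided convention remains the default of the
standalone p-value functions.

### Decision rule and variable selection

AUROCs and p-values over partitions are summarized by medians (they are
not normal). The classifier is accepted only if median AUROC ≥ 0.8 **and**
median p ≤ 0.05; only then are variables selected, as those with median
VIP > 1 across all models (per-model VIP > 1 is the usual single-model
rule; the median is the natural aggregate over a model ensemble and is
stable against the occasional degenerate fit). Loading signs are available
from the per-model stream for interpreting the direction of selected
variables, but the decision uses VIP only. Results stream to JSON-lines,
so the full 208,104-model run needs constant memory; the default CLI cap
is 5,000 models with `--full` for the complete sweep.

## Synthetic cohort generator

The generator's role is to produce data with the statistical structure the
analysis assumes, at the study's own scale, so every stage is testable.

- **Concentrations** are log-normal, moment-matched to the configured
  arithmetic mean ± sd per group — strictly positive and right-skewed, as
  serum concentrations are; published group summaries are reproduced
  exactly in expectation. Defaults carry the five published group effects
  (SDMA 0.57 ± 0.15 vs 0.52 ± 0.07; SM C20:2 0.29 ± 0.07 vs 0.25 ± 0.05;
  lysoPC a C17:0, PC aa C40:6, PC aa C42:3 lowered in cases), all in
  µmol/L; remaining metabolites draw family-typical baselines from fixed
  internal ranges so the panel is identical across seeds.
- **Matching** is modeled as a shared pair-level intercept on the
  standardized log scale with correlation 0.3 (matching-induced
  correlation is never published; 0.3 is a moderate value for clinically
  matched subjects), plus pair-matched age and sex. Hypertension is
  group-dependent (56.3% cases vs 25.0% controls).
- **Biomarkers** use the published group means ± sd (CK peak
  3466 ± 2211 vs 2394 ± 1615 UI/L, CRP 35.9 ± 44.3 vs 21.7 ± 30.4 mg/L,
  etc.) with the same log-normal pairing scheme.
- **Censoring**: quantitation limits sit at the quantiles of the pooled
  log-normal corresponding to each metabolite's configured out-of-range
  probability, split across both tails — 0.02 for the 142 panel slots
  designed to pass and 0.60 for the 46 designed to fail, far enough from
  the 20% threshold that the 142/188 outcome is stable for any seed at 64
  samples.
- **Null mode** replaces every case parameter (metabolites, biomarkers,
  hypertension rate) with its control counterpart, so labels are
  exchangeable by construction.

What the generator does **not** emulate: plate/batch effects, QC-sample
drift, metabolite-metabolite correlation beyond the shared pair intercept,
covariate-metabolite coupling, missingness mechanisms, or any raw
mass-spectrometry structure. Passing tests therefore demonstrate that the
*procedures* behave as specified on data satisfying their assumptions —
not that the original cohort's data-dependent results (median AUROC 0.48,
11% significant models, specific univariate p-values) are recovered; those
depend on undeposited patient data and are out of reach by design.

## Problem sizes and determinism

The test suite and the acceptance script use systematically thinned plans
(tens to 2,000 models) and replicate-cohort simulations (200–400
replicates) — sizes chosen so the full suite runs in well under a minute
while keeping binomial/Monte-Carlo error small relative to the tolerances
tested. The full 208,104-model sweep on a 64 × 142 matrix is a single
`--full` CLI run (PLS1 fits are closed-form per component, ~1 ms per
model). All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical config + seed reproduces every
matrix, stream and report bit-for-bit.

Because 2,000 partitions of one 32-pair cohort share the same subjects,
their results are strongly dependent: the significant-model fraction of a
single cohort has a standard deviation of ~10 percentage points around its
calibrated mean. Calibration statements at binomial precision are
therefore always made by pooling models across independent replicate
cohorts, as both the acceptance script and the calibration tests do.

## Known limitations

- The mirrored-pair null assumes a linear scoring function and complete
  two-member pairs; larger sibships fall back to generic pair-mean
  centering, where the mirror identity no longer holds exactly.
- The exact Mann–Whitney null ignores ties in test scores (continuous
  scores make ties measure-zero; heavily discretized inputs would need a
  tie-adjusted null).
- BH correction assumes the usual PRDS-type dependence; metabolite panels
  with strong negative dependence would need Benjamini–Yekutieli.
- The generator's independence across metabolites makes multivariate
  detection *easier* than on real correlated panels at the same per-
  variable effect size; power numbers from synthetic runs are optimistic
  in that respect.
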