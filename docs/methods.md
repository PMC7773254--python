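# Methods

This note records the statistical model behind each framework, the
defaults and numerical choices, what the synthetic-data generator does
and does not emulate, and the known limitations.

## The screening regime

Every analysis compares one mutant line against wild-type controls on a
single response, one row per specimen. The design the engine targets is
strongly unbalanced: hundreds of controls accumulated over many
measurement batches, and a mutant cohort of about 14 animals (7 per
sex) measured in a handful of recent batches. All defaults below are
chosen for this regime.

## Layer 1–2: preparation

* **Terminology normalization.** Column names are unified through a
  packaged synonym dictionary (`synonyms.json`, user-extendable):
  `sex`/`gender` → `Sex`, `weight`/`body_weight` → `BodyWeight`,
  `batch`/`date_of_experiment`/`assay_date` → `Batch`,
  `genotype`/`biological_sample_group` → `Genotype`. Sex levels are
  harmonized (`f`/`female` → `Female`, `m`/`male` → `Male`). Two input
  columns colliding onto one unified name is an error, not a guess.
* **Missing values.** A variable whose missing fraction strictly
  exceeds the threshold (default 0.5) is dropped, unless the caller
  supplies a substitution value, in which case missings are filled and
  counted. Row-level missingness is handled later, per fitted model:
  each model drops only rows missing in the variables *it* uses
  (complete-case analysis), so an unused ragged covariate never costs
  observations.
* **Redundancy.** Duplicated columns, and numeric pairs with
  |Pearson r| = 1 on complete cases (tolerance 1e−12 to absorb
  floating-point noise in exactly collinear pairs), are reduced to the
  column appearing first in the file — deterministic and explainable.
  Constant columns are flagged but kept unless a model needs them.
* **Validation.** The model spec is bound to the data with hard errors
  for unfixable problems (no Genotype, fewer than two genotype levels,
  unobserved reference level, response type incompatible with the
  framework) and recorded degradations for fixable ones: Sex terms are
  dropped when one sex is observed, terms whose columns were removed
  upstream are dropped, and a single-level random group triggers the
  fixed-effects-only fallback. Genotype is never silently dropped.
  When no reference level is named, a level whose label looks like a
  control (`control`, `WT`, `+/+`, …) is used; otherwise binding fails.

## Linear mixed model

The default model is `Response = Genotype + Sex + Genotype:Sex +
BodyWeight` with a `Batch` random intercept, fitted with statsmodels'
`MixedLM`. Categorical terms are treatment-coded against a sorted
reference level (Genotype against the designated control), interactions
are products of the coded columns, and rank-deficient design columns
are removed greedily in column order and recorded.

* **Likelihoods.** Model comparison uses maximum likelihood, because
  REML likelihoods are not comparable across fixed-effect structures;
  the final reported model is refit by REML. AICc counts k = fixed
  coefficients + variance components (batch and residual; one fewer in
  the fixed-only fallback).
* **Selection.** Backward search starts from the full model and removes
  the single term that most lowers AICc; forward starts from
  Genotype-only; stepwise alternates removal and addition until a fixed
  point (visited term sets are tracked so the search terminates).
  Genotype is never a candidate; an interaction may only appear with
  both main effects. AICc ties within 1e−8 resolve in favour of the
  smaller model. Every candidate evaluation is recorded in the trace.
  Candidate fits are fitted cold — at screening sizes a fit takes tens
  of milliseconds, and cold fits make selection trivially independent
  of visit order (refitting the selected model cold reproduces its
  estimates exactly).
* **Inference.** Wald normal-approximation 95% CIs and p-values for all
  fixed effects. No degrees-of-freedom correction is applied; this is a
  documented limitation (see below).
* **Sub-models.** The overall genotype contrast comes from the model
  without the Genotype×Sex interaction. Sex-specific effects come from
  the interaction parameterisation: with Female as the reference sex,
  the genotype coefficient is the female effect and its sum with the
  interaction coefficient is the male effect, with a delta-method SE
  from the fixed-effect covariance. The interaction's own Wald test is
  the dimorphism test. Sex-specific entries are omitted when one sex is
  observed.
* **Effect sizes.** Numeric predictors: standardized coefficient
  β·SD(x)/SD(y). Genotype contrast: a Cohen's-d analogue
  β/√(σ²_batch + σ²), i.e. the shift in units of the total outcome SD.
  CIs are the Wald CI scaled by the same factor.
* **Diagnostics.** Shapiro–Wilk and Kolmogorov–Smirnov (against a
  normal with the residuals' moments) on conditional residuals, plus
  min/max/skewness. Above 5000 residuals, Shapiro–Wilk uses a seeded
  subsample of 5000 (the test's valid range); below 3 it is omitted
  with a reason. When the estimated batch variance is zero the BLUPs
  are zero and marginal residuals are used directly.
* **Non-convergence.** The optimizer is retried (`bfgs`, then `cg`,
  then `powell`); a still-unconverged fit is returned flagged rather
  than raised, so one bad dataset cannot halt a screen.

## Fisher framework

All three p-value routes implement one two-sided convention: the total
null probability of margin-fixed tables whose probability is at most
the observed table's, with relative tolerance 1 + 1e−7 (the standard
convention; it protects against float noise deciding inclusion).

* **2×2**: hypergeometric enumeration over the support. Odds ratio
  ad/bc with a log-odds normal CI; the Haldane–Anscombe 0.5 correction
  is applied only when a zero cell is present.
* **r×c enumeration**: recursion over rows with margin-feasibility
  pruning, multivariate hypergeometric probabilities via cached
  log-factorials; bounded at 10⁶ tables. If every table is as extreme
  as the observed one the p-value is exactly 1 (avoiding accumulation
  error in a sum that should be 1). The enumerated distribution itself
  is exposed for normalization checks.
* **Monte-Carlo**: tables are drawn with both margins fixed by filling
  rows sequentially with multivariate hypergeometric draws against the
  remaining column margins — the classical fill-by-row construction —
  from a seeded generator, so identical seed/table/B give bit-identical
  p. The statistic is the table's null probability (not a chi-square
  surrogate), so the simulated p targets exactly the enumerated p; the
  add-one estimator (1 + hits)/(B + 1) keeps p positive. Default
  B = 10000.
* **Strata**: the whole dataset, each sex, each life stage, and
  sex×lifestage cells, tested independently (no pooled
  Cochran–Mantel–Haenszel test, by design). Tables reduced below 2×2
  after dropping empty response categories are reported "not testable"
  rather than raising. Effect size: 100 × max absolute difference in
  within-genotype category proportions between a mutant column and the
  reference column.

## Reference Range Plus

Coverage q (default 0.95) is split symmetrically: thresholds at the
(1−q)/2 and 1−(1−q)/2 linear-interpolation empirical quantiles of the
*controls of the same stratum* (sex-specific tests use sex-matched
controls). Band boundaries classify as Normal — the conservative
direction. Tie handling: if more controls fall strictly outside a
threshold than that tail's budget n(1−q)/2 allows (which happens when a
tie mass straddles the quantile position), the threshold moves outward
to the nearest strictly distinct order statistic; a threshold landing
on a tied value also sets the `adjusted` flag. Adjustment can only
widen the band, so the achieved coverage `q_effective` never falls
below q, and no control sharing a threshold value is ever classed
outside Normal. Both collapsed directions are tested with the exact
2×2 path; a direction with an empty margin (e.g. nobody High) is
reported degenerate with its p absent instead of raising.

## Reporting

The bundle carries schema version, metadata (tool version, seed, input
SHA-256, optional timestamp), dataset summary, preparation record, the
applied post-degradation model, the framework result, and a status in
{OK, Degraded, NotTestable, Failed} with reasons. The genotype p-value
is surfaced at the fixed top-level key `genotype_pvalue` for downstream
databases. Serialization is deterministic (fixed key order,
round-trippable floats); NaN/±inf become `null` with a
`<key>_nonfinite` sibling flag. A structural validator ships with the
package and runs on every serialization.

## Synthetic data

The generator emulates the screening regime: controls assigned
round-robin to weekly batches, mutants confined to the last 3 batches
(as in real screens, where controls accumulate long before a line is
measured), body weight drawn sex-dependently (22 g female / 27 g male,
SD 1.5) so bodyweight–sex confounding is representable, batch random
intercepts (default SD 0.5) and unit residual SD, with configurable
effect sizes, missingness and tie coarsening. Defaults are 400 controls
over 20 batches and 7 mutants per sex. The categorical generator draws
per-genotype category probabilities (default: a rare event at 5%).
Everything is a pure function of the seed.

What it does **not** emulate: seasonal drift or time-varying batch
effects, outlier contamination, heteroscedastic residuals, litter
structure, or repeated measures. Passing calibration tests on this
generator therefore shows correctness of the estimator under its own
assumptions — not robustness to real-data violations of them, which is
what the residual diagnostics are reported for.

## Problem sizes used by the tests and the acceptance script

The statistical checks use 500 replicates for CI coverage, 1000 per
framework for type-I calibration, 200 for the selection-rate checks and
a 20-table enumerable battery at B = 20000 for Monte-Carlo agreement.
The acceptance script recomputes the same quantities at 250/400–1000/100
replicates — sizes chosen to keep a full from-scratch rerun to a few
minutes on one CPU while leaving binomial noise well inside the margins
the quantities are judged by.

## Known limitations

* Wald inference without degrees-of-freedom correction can be slightly
  anticonservative when the number of batches is small; with ≥ 20
  batches the simulated type-I rate is within the binomial band of the
  nominal level.
* Heterogeneous residual variance per genotype is not implemented; the
  mixed-model backend estimates a single residual variance.
* No multiple-testing correction across datasets: a screening pipeline
  reports raw per-dataset p-values and corrects downstream.
* The enumeration bound (10⁶ tables) is generous for screening-sized
  tables but large sparse tables fall back to Monte-Carlo, whose p
  carries simulation error of order √(p(1−p)/B).
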