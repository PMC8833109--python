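# Methods

This note documents the models implemented in `omiclocks`, the synthetic
study conditions, the numerical choices, and the points where the design
was genuinely open.

## Synthetic cohort model

The generator produces the statistical structure the analysis consumes and
nothing more (no attempt at methylation beta-value distributions, glycan
chemistry or NMR spectra — only the moment structure).

* **chronAge** is uniform on the configured range (default 16–100 years).
  Only the range of the emulated design is known, not the distribution's
  shape; uniform maximises spread for clock training and is stated as an
  assumption, not a fact about any real cohort.
* **Latent acceleration.** Each individual carries a scalar biological-age
  acceleration δ ~ N(0, σ_δ²), default σ_δ = 5 years — large enough that an
  accurate clock's OCAA can carry signal, small relative to the 24-year SD
  of chronAge. δ is written to `truth.tsv` for tests and oracles only; the
  pipeline never reads it. A multi-component acceleration is a plausible
  extension; the default model deliberately has one component, so
  "excess overlap" between synthetic clocks is high by construction.
* **Omics features.** Feature j of assay k is
  `a_kj·z(chronAge) + b_kj·z(δ) + batch + N(0, noise²)`, with loadings
  drawn once per feature from half-normal distributions scaled by the
  assay spec, an additive batch shift (level per individual, shift per
  level×feature), whole-assay coverage < 1 and sparse cell-level
  missingness. The four default assays are graded so trained clocks span
  test-set chronAge correlations of roughly 0.2–0.97 (at n = 1000 the
  defaults give 0.21, 0.66, 0.87 and 0.97), emulating the spread seen
  across real platforms from weakly age-informative metabolomics up to
  CpG panels. Coverage and missingness defaults keep the
  complete-on-all-assays pool comfortably larger than the 25% test
  sample, since the split draws test individuals from that pool first.
* **Risk factors** are linear in chronAge, δ, sex and smoking plus
  Gaussian noise; units are arbitrary because the association stage
  standardises outcomes.
* **Disease.** Event times are exponential with rate
  `baseline_rate·exp(log_hr_age·age + log_hr_delta·δ + log_hr_sex·sex)`,
  censored at end of follow-up (default 10 years). The default per-year
  chronAge log hazard is 0.0492 (risk doubling every ln2/0.0492 ≈ 14
  years). Prevalent cases are generated by running the same hazard
  backwards over the prevalence window, so the prevalent-exclusion filter
  is exercised; an individual's prevalent row has a negative event time.
  Baseline rates are set so each block yields tens of incident events per
  1000 individuals over follow-up.
* **Randomness.** Every stream is
  `SeedSequence([seed, stage_index, within_stage_index])` with frozen
  stage indices, so stages regenerate independently and identical configs
  give byte-identical TSV outputs.

## Quality control

Fixed, logged order per assay: first-pass outliers (|z| > 6, set missing)
→ fixed-effects covariate pre-correction (categoricals expanded to
indicators; aliased columns dropped by pivoted QR and logged) → optional
second-pass outliers (z > 3) → scaling/centring to mean 0, SD 1 with
constant features dropped. Outlier passes are single-shot, not iterated.
Second-pass z-scores are computed on the post-correction residual
distribution: the correction itself changes the scale, and residual
outliers are what the second pass is for. Missing values are excluded
pairwise from means/SDs; complete-case filtering happens only per assay at
clock-training time. Sex is always a pre-correction covariate for features
but is retained as a model covariate in the association stage.

## Clock construction

Elastic net (mixing α, penalty λ — the glmnet vocabulary; scikit-learn's
`ElasticNetCV` with `l1_ratio = α` stands behind the fit). λ is chosen at
minimum mean CV MSE over a tenfold split, not the 1-SE rule. Features are
standardised with training-set statistics only and test rows transformed
with the stored statistics, preventing leakage; the penalised-regression
literature is silent on this and the choice is conservative. LASSO
(α = 1), fixed α = 0.5 and CV-selected α are all available and give
test-set correlations within 0.03 of each other on informative synthetic
assays.

Stability selection redraws the 75/25 split per iteration (default 500
iterations; per-iteration seeds are `SeedSequence([seed, i])`, so results
are independent of execution order and parallelisable by contract) and
keeps features selected in >95% of iterations. The core clock re-runs the
full procedure — fresh CV for λ, refit intercept — on the core feature
set; whether published core-panel clocks refit or freeze coefficients is
not generally stated, and re-running the full procedure is the
self-consistent choice. The mega matrix merges corrected, standardised
assays on the intersection of individuals, with assay-prefixed feature
ids. PC clocks compute components on complete training rows only and
store the loadings plus feature statistics so new individuals are
projected before the elastic-net step.

A caution that the synthetic model makes vivid: corr(OCAA, δ) rises with
the δ-loading/noise ratio only in the weak-loading regime. When features
load strongly on δ, the penalised fit partially cancels the acceleration
direction while predicting chronAge, and OCAA tracks δ *less* — the
synthetic counterpart of near-perfect clocks having uninformative
accelerations.

## Fixed-coefficient clocks and the glycan score

A generic applier evaluates intercept + Σ w·transform(feature) with
per-feature transforms limited to {identity, square}; published
coefficient tables themselves are deliberately not shipped. The IgG-glycan
age score regresses chronAge on {GP6, GP6², GP14, GP15} separately per
sex and scores fitted-minus-observed age. The published recipe's phrasing
is ambiguous about regression direction; regressing chronAge *on* the
glycan terms is the prediction-style reading consistent with every other
clock, and the fitted-minus-observed sign makes positive = accelerated.
Within-sex centring is then automatic (least-squares residuals have zero
mean per stratum), so the score cannot carry between-sex level
differences.

## Variance partition and excess overlap

Part correlations use the leave-one-out R² identity
sr_i² = R²(all) − R²(all−i) — numerically stable, and independently
checked in the tests against the classic residualisation formula and
against `pingouin`'s semi-partial correlation. Negative numerical
variances below −1e-9 warn before flooring at 0; perfectly collinear
clock pairs report 0 unique variance with a warning. The k-clock
partition uses the complete-case intersection across all clocks; pairwise
overlap uses each pair's own intersection. The mega clock is excluded
from all between-clock comparisons by default (its feature set spans
every assay, making overlap structural), overridable by argument.

For the pairwise statistic, observed bivariate R² slightly outside
[E_min, E_max] (sampling noise) is clamped with a warning; E = E_min
(e.g. one clock explains nothing) makes the statistic undefined and
returns NaN with an explanation.

**The ISLSP null, made exact.** The null model imagines a complete latent
set of p equal-variance independent predictors of standardised chronAge,
with each clock built from an independently sampled subset. The expected
joint explained variance E = 1 − (1−v₁)(1−v₂) equals the expected
*union coverage* of the two subsets. The package therefore formalises the
null by scoring a bank-clock pair's observed overlap O as the R² of
chronAge on the union of their predictor subsets: with subset overlap at
its hypergeometric expectation this reproduces E exactly and the
statistic is 0 to machine precision, and over random independent draws it
centres on 0. (Regressing chronAge on the two clock *scores* instead
gives a smaller O — for 50/50 subsets overlapping in 25 of 100, 2/3
rather than 3/4 — because two scalar scores span less than their feature
union; the union reading is the one under which the independent-sampling
benchmark is self-consistent.) The bank itself is constructed exactly:
a centred Gaussian matrix is orthonormalised by QR and rescaled, so
empirical subset regressions return |subset|/p to machine precision.

## Health associations

One-sided p-values are normal tail probabilities of the Wald z (H1: the
effect increases risk). Screening eligibility — positive chronAge effect,
BH-FDR < 10% within the outcome family, >5 incident cases for disease —
gates every OCAA test; ineligible outcomes never enter the results. FDR
families are one per outcome type per analysis. Cox fits use lifelines
(Efron ties) with time since assessment as the baseline axis and
prevalent cases excluded entirely; non-converged fits are flagged and
excluded from IVW aggregation with a logged reason; constant covariates
(e.g. sex inside a single-sex stratum) are dropped before fitting.

Rescaling divides the OCAA effect by a chronAge effect: trait-by-trait
for risk factors, taking the chronAge coefficient from the same adjusted
model used for screening (the marginal-vs-adjusted choice is not
documented for the original analysis; using one model for numerator and
divisor keeps the ratio internally consistent), and a single pooled
divisor of magnitude 0.0492 log HR/year for all disease groups. The
pooled value is sometimes quoted with a negative sign; since eligibility
requires risk to *rise* with age, the divisor is applied by magnitude.
Shrinkage is the conjugate normal-normal posterior mean β/(1+se²) under
a N(0,1) prior. IVW standard errors assume independence that correlated
outcomes violate; they are labelled indicative throughout.

The sex-consistency procedure restricts to pooled nominal hits
(one-sided p < 0.05), re-screens per sex under the same eligibility rule,
refits OCAA models in each sex for outcomes eligible in both, counts sign
agreement, and applies a two-sided normal difference test to discrepant
pairs.

Clock–outcome exclusion rules (a clinical-measures clock never tested
against risk factors; creatinine and cholesterol never tested against
metabolite/lipid clocks that measure them) ship as an editable config
table; entries that match no clock in a run are inert.

## Pipeline

Stages communicate only through TSV/JSON files in a run directory; each
stage's outputs are SHA-256-digested into a manifest, and a stage is
skipped on rerun when its sentinel outputs exist, so deleting one stage's
files recomputes only downstream work. Floats are written with a fixed
`%.10g` format so identical configs give identical digests. Associations
use test-sample OCAAs only: training-sample accelerations are overfit and
would bias effect estimates toward the training noise.

## Problem sizes and limitations

Tests run the pipeline at a few hundred to a few thousand individuals and
parameter-recovery checks at n = 10000–20000, sizes at which the Cox and
linear estimators are comfortably within 2 SE of the generating values.
Passing tests show the machinery is correct under the generator's
assumptions — linear feature loadings, a single latent acceleration,
exponential event times, uninformative censoring. They do not show that
any real assay satisfies those assumptions, and the synthetic defaults
make no claim to reproduce any real cohort's effect sizes; real-data
headline numbers are reproduced as procedure shapes and qualitative
orderings only (shared variance dominating unique variance; positive
excess overlap among clocks of a common signal; attenuation of rescaled
effects with clock noise). Mortality outcomes and competing risks are out
of scope, as is any platform-specific raw QC.
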