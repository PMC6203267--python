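# Methods

This note documents the models implemented in `materwell`, the
synthetic-cohort generator used to validate them, and the design
decisions taken where more than one reasonable convention exists.

## Cohort structure and scale scoring

A cohort is one row per mother/child dyad: syndrome group (ASD
reference plus 13 genetic syndromes), child age (years, ≥ 2), maternal
age (years), child gender, a Wessex self-help score (integers 3–9, with
9 the maximum; only the "at maximum vs below" contrast is used
analytically), and four questionnaire outcomes:

| measure | items | item range | score range | scoring |
|---|---|---|---|---|
| PGS | 7 | 1–5 | 7–35 | sum of reverse-coded items (1↔5, 2↔4) |
| PAS5 | 5 | 1–5 | 5–25 | sum |
| HADS-D | 7 | 0–3 | 0–21 | sum; > 7 is clinically significant |
| QRSF stress | 7 | true/false | 0–7 | count of "true" |

Scales with at least 75% of items answered are prorated (mean of
answered items × item count, rounded half-up — the standard psychometric
convention; the scoring threshold is configurable and applied per
scale). Scales below 75% completion are missing, never zero. Exclusion
filtering removes, in order: non-mother respondents, children younger
than 2, records under 75% completion on any analysed scale, and ASD
records with a Social Communication Questionnaire total below 15
(scoring exactly 15 is retained); the returned ledger counts each
removed record once, under the first rule it failed.

`cronbach_alpha` implements the internal-consistency coefficient
α = k/(k−1)·(1 − Σ item variances / total variance) with (n−1)
variances on listwise-complete rows; on dichotomous items it equals
KR-20 exactly (asserted against an independent KR-20 implementation in
the tests).

## The synthetic-cohort generator

The generator's defaults emulate the study layout: 14 groups totalling
712 dyads (ASD 66, AS 28, CdLS 44, DS 29, FXS 102, PMS 31, PWS 101,
RTT 87, RTS 47, SMS 20, Sotos 38, TSC 71, 1p36 26, 8p23 22), per-group
child/maternal age means and sds (ages drawn from normals truncated at
2 and 18 years respectively — the distributional family is a modelling
choice; only means and sds are constrained), per-group proportions of
male children, and per-group probabilities that the Wessex self-help
score is at its maximum (Rett's proportion is not reported anywhere and
is set to 0.05, reflecting the syndrome's severe self-help impairment;
below-maximum scores are uniform on 3–8, which is immaterial because
only the at-maximum contrast is analysed). Dyads are independent; there
is no family clustering. SCQ totals are generated for the ASD group
only, where the cut-off applies.

Outcomes follow a latent-variable scheme per measure:

1. latent scale score s = group mean + covariate effects (child age and
   maternal age centered at the cohort-typical 15.2 / 46.6 years,
   Wessex-at-maximum shift, optional group-set × covariate
   interactions) + N(0, person_sd²);
2. each item's pre-discretization value is s/k + N(0, item_sd²);
3. items are discretized by randomized rounding (floor plus a Bernoulli
   on the fractional part) and clipped to the item range. True/false
   items are the 0–1 special case, i.e. a Bernoulli draw.

Randomized rounding is mean-unbiased and clipping is the only source of
bias, with a censored-normal closed form; the generator therefore
records the *exact* expected scale score per dyad (k times the censored
mean of N(μ/k, (person_sd/k)² + item_sd²) over the item range) in its
latent-truth output. Recovery and coverage tests target this exact
expectation, not the nominal latent mean, so they test the samplers and
nothing else.

Default latent group means are the study-condition profile (e.g. HADS
7.12 for ASD down to 4.70 for Rett); default dispersions
(person_sd/item_sd: PGS 3.2/0.6, PAS5 2.0/0.6, HADS 2.3/0.5, stress
1.6/0.3) give realistic scale-score spreads. The `person_sd` component
exists because questionnaire items share a person-level factor; without
it a 7-item sum cannot reach realistic dispersion while keeping items in
range. What the generator does **not** emulate: item-level factor
structure beyond a single person factor, informative missingness
(missingness is independent per item), response styles, and family
clustering — so passing tests demonstrate correctness of the estimation
machinery under the study's design, not robustness to those real-data
features.

The full configuration round-trips through YAML
(`load_cohort_config` / `save_cohort_config`); the bundled
`data/study_cohort.yaml` reproduces the default layout.

## Stage 1: Bayesian linear regression

For each continuous measure, `y ~ N(Xβ, σ²)` with ASD as the base level
(intercept) and one 0/1 difference column per other group; rows missing
the response are dropped per measure (complete case per outcome, so
different measures may use different subsamples). Priors are independent
normals, N(η_A, ε_A²) on the intercept and N(η_B, ε_B²) on every other
column, and InvGamma(ν, ω) on σ². The ε are standard deviations; ν and
ω are the inverse-gamma shape and scale used directly as given (0.001,
0.001), not the halved convention of some software — both conventions
can be expressed through `PriorSpec`.

The Gibbs sampler alternates the exact conditionals
`β | σ² ~ N(V_n(V₀⁻¹m₀ + X'y/σ²), V_n)` with
`V_n = (V₀⁻¹ + X'X/σ²)⁻¹`, and
`σ² | β ~ InvGamma(ν + n/2, ω + RSS/2)`. Defaults: 20,000 iterations,
2,000 burn-in, thin 1. With zero data rows the conditionals collapse to
the prior, which the tests exploit for exact prior recovery. A gamma
draw with shape 0.001 can underflow to zero; it is clamped at the
smallest positive float.

Conventions for the reported functionals, each a deliberate choice
where several definitions exist:

- **Probability of difference from ASD** = max(P(β_diff > 0),
  P(β_diff < 0)) over posterior draws. This maps "indistinguishable" to
  0.5 and "certainly different" to 1, matching how such probabilities
  are read in group-comparison tables.
- **Clinical depression probability** = posterior predictive
  P(ỹ > 7) with ỹ | β, σ² ~ N(μ_group, σ²), averaged over draws
  (`mode="integrate"`); a plug-in mode evaluating at posterior means is
  also provided since either could underlie a published figure. At
  σ → 0 with μ exactly at the cut-off the value is 0.5 by continuity.
  The cut-off (7 = upper end of the HADS "normal" band) is
  configurable.
- **Similarity grouping** of syndromes (the shaded clusters in
  caterpillar displays) is a greedy agglomeration: groups ordered by
  posterior mean join the current cluster while their pairwise
  probability of difference with every member stays below 0.9
  (configurable); deterministic given the draws.

Validation: the sampler's posterior moments for β and σ² agree with a
dense-grid numerical posterior (β integrated analytically conditional
on σ², σ² on a 4,000-point log grid) within 3 Monte-Carlo standard
errors on a fixed n = 30 dataset; with no data the Table-of-priors
moments are recovered to ±0.02; and over 200 synthetic cohorts at the
712-dyad layout with true coefficients drawn from the prior (the
standard simulation-based calibration design) the 90% credible
intervals cover the exact generator expectations 85–95% of the time.

## Stage 2: CART

A hand-written deterministic regression tree: splits minimize the
summed within-child SSE; candidate thresholds are the observed covariate
values with "x ≤ t" going left (matching the ≤/> notation of the
reported dichotomies); ties break toward the smaller threshold, then
earlier covariate. Defaults max_depth 3, min_leaf 20, minimum split
improvement 1% of the parent SSE — shallow by design, because the tree's
only job is to propose coarse dichotomization thresholds for stage 3;
there is no pruning or cross-validation. The Wessex variable is offered
both raw and as the at-maximum indicator. Thresholds such as "child age
≤ 8" are data-dependent outputs, never constants. The library tree is
cross-checked against scikit-learn's regressor on data with an
unambiguous split (identical partitions; the split *points* differ
because scikit-learn uses midpoints).

## Stage 3: Bayesian model averaging

Candidates are syndrome-partition indicators taken from the stage-1
similarity clusters (lowest-mean cluster as baseline), CART threshold
indicators, and partition × threshold interactions (included because
group-specific covariate effects are part of the analysis questions).
Interactions are admissible only alongside both parents (hierarchy,
configurable). All admissible subsets are enumerated exhaustively — the
candidate count is capped (12 in the pipeline, hard guard at 20) so
enumeration stays exact and fast; model-space sampling is deliberately
out of scope.

Marginal likelihoods use a Zellner g-prior on the slopes with reference
priors on intercept and σ² (see the README for the closed form);
g = n (unit information) by default. Posterior model probabilities
follow from a uniform model prior; inclusion probabilities sum the
probabilities of models containing each predictor; model-averaged
coefficient means and sds combine the per-model scaled-t posteriors
(mean g/(1+g)·β̂_OLS) by the law of total variance, with excluded
models contributing zero. Rank-deficient models are dropped with a
logged warning and the probabilities renormalized — this is also the
collinearity guard: a predictor duplicated under two names splits its
inclusion mass but can never be selected jointly.

A different Bayesian variable-selection prior (for example the
mixture-g priors common in BMA software) would shift the numeric
inclusion probabilities; results under the fixed g-prior are therefore
comparable across runs of this package but only qualitatively
comparable with other implementations. The closed form is verified to
1e−10 against an independent determinant-route recomputation and to
1e−6 against tensor-grid quadrature of the same prior.

## Stress: ordinal probit by data augmentation

The 0–7 stress count is modelled through a latent level
z = x'β + e, e ~ N(0, 1), with category k ⇔ z ∈ (γ_{k−1}, γ_k].
Identification fixes the first finite cutpoint at 0, keeps unit latent
variance, and puts the intercept in β; slopes have vague N(0, 10²)
priors and cutpoints a flat order-constrained prior. The Gibbs sweep
alternates truncated-normal latent utilities, the conjugate normal
update for β, and uniform conditional updates for each interior
cutpoint. The default design is the joint model: group indicators,
Wessex-at-maximum, child age, and syndrome × age interactions (opposite
age trends in different syndromes are an expected pattern); a per-group
model can be assembled from the same functions.

Uniform cutpoint updates are known to mix slowly (their conditional
interval shrinks like 1/n), which is handled two ways: the default
iteration count for stress runs is high (50,000, burn-in 5,000, thin
10), and the chain starts at the maximum-likelihood ordered probit
(statsmodels `OrderedModel`), falling back to empirical-CDF probit
quantiles when the MLE is unavailable (e.g. unobserved categories).
A collapsed/hybrid cutpoint update would be the natural extension if
much longer chains were needed. Categories with zero observations get
cutpoints sampled from the neighbour-admissible range, with a warning.

Reported functionals: posterior-averaged category probabilities
P(score = k | profile) = Φ(γ_k − x'β) − Φ(γ_{k−1} − x'β) (they sum to 1
by construction); the predictive median (lower-median convention on
ties: a uniform predictive over 0–7 reports 3) with a central 90%
interval by CDF inversion on the category scale; and the **age-trend
posterior p-value** min(P(slope ≤ 0), P(slope ≥ 0)) of a group's total
age slope (global plus interaction), reported with the sign of the
posterior mean — small values indicate a credible monotone trend. The
tail-probability definition is a documented choice; "Bayesian posterior
p-value" has no unique definition.

Validation: slopes (1.0, −0.5) recovered within 0.1 at n = 2,000; the
two-category collapse reproduces the binary probit MLE within a
posterior sd at n = 1,000; cutpoints are strictly increasing in every
retained draw; 90% intervals for the slopes cover the truth 85–95% of
the time over 100 recovery replicates.

## Pipeline, seeds and outputs

`run_pipeline` executes, per continuous measure, stage 1 → CART → BMA,
and for stress CART → ordinal probit (no BMA — the outcome is an
ordered count, and the CART-discovered factorizations feed the probit
design). Stage seeds derive deterministically from the master seed and
the stage name (CRC-32 into a seed sequence), so reruns are
byte-identical and any stage can be re-run in isolation. All tables are
CSV with fixed float formatting and missing values as empty fields; the
manifest is a plain-text key=value file recording version, seeds,
cluster assignments and the conventions exercised, and marks a run
incomplete until the last artifact is written. Stage failures abort
with the stage name. Table-3-style stress medians are reported at the
below-maximum Wessex profile and the cohort-mean child age; the
Fig-4-style profile table evaluates ages 8 and 16 by default.

## Problem sizes and numerics

The test suite and the acceptance script size their simulations so the
whole validation runs in minutes on one CPU: the oracle-equivalence
dataset is n = 30; prior recovery uses 10⁵ draws; coverage uses 200
cohorts of 712 dyads with 2,200-iteration chains; ordinal recovery uses
n = 2,000 with 5,000 iterations; the determinism check runs the full
pipeline twice at 1,500 iterations. These sizes are validation choices;
production defaults (20,000 / 50,000 iterations) are set on the
`AnalysisConfig`. Numerical safeguards worth knowing about: quantile
intervals use linear-interpolation sample quantiles; the degenerate
σ = 0 predictive is resolved by continuity; truncated-normal sampling
clips CDF values away from 0/1; tree tie-breaks and the greedy
clustering are fully deterministic.

## Known limitations

- The BMA inclusion probabilities depend on the g-prior; no
  mixture-of-g or Zellner–Siow alternatives are provided.
- No convergence diagnostics beyond effective sample size are computed;
  the samplers here are conjugate or near-conjugate and validated
  against oracles, but unusual configurations deserve trace inspection.
- Stress is analysed only as the 0–7 total (no item-level IRT model),
  and no proportional-odds logistic alternative is offered.
- The generator's missingness is completely at random; the 75%
  completion rule is applied per scale (whether the original rule was
  per scale or per questionnaire pack is not determinable, so it is
  configurable).
- Plotting is intentionally out of scope; every figure-equivalent
  quantity is emitted as a table.
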