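# Methods

This note documents the models implemented in `trendmr`, the choices made
where the design was genuinely open, and what the synthetic-data experiments
do and do not establish.

## Dose-response trend from categorical tables

**Model.** Each published cohort table reports adjusted relative risks
`RR_i` for ordered height categories against a shared reference category,
plus cases and denominators per category. We assume a log-linear
association: `log RR(h) = beta * (h - h_ref)`. Because all non-reference
categories are contrasted with the same reference group, the category log
RRs are positively correlated; treating them as independent understates the
trend's standard error.

**Pseudo-counts.** The reconstruction solves for a table of pseudo-cases
consistent with (i) the adjusted RRs exactly and (ii) the observed margins
(per-category denominators and the total case count). Given the reference
cell `A_0`, every other pseudo-cell follows from the design-specific RR
formula (rate ratio, risk ratio, or odds ratio); `A_0` is found by Newton
iteration on the total-cases equation (tolerance 1e-10 on the margin
residual, max 100 iterations, steps damped to stay inside `(0, N_0)`).
For rate and cumulative-incidence designs the margin equation is linear in
`A_0` and converges in one step; the case-control design is genuinely
nonlinear. The covariance of the non-reference log RRs then uses Woolf-type
formulas, with the reference-cell terms shared off-diagonally.

**Scores.** Reported category means/medians are used verbatim. Otherwise
closed intervals get midpoints and an open-ended extreme interval gets the
adjacent closed interval's boundary plus/minus half that interval's width —
a deterministic rule matching common practice for open quantiles. Two
adjacent open intervals are an error.

**Fallback.** When per-category counts are unavailable the trend is fitted
with independent CI-derived weights and labelled
`independence_fallback`. Note the direction of the approximation error:
dropping the positive shared-reference covariance makes the trend look
*more* precise than the full GLS fit, so fallback standard errors should be
read as lower bounds.

**Units.** Trends are estimated per cm of the score scale and rescaled
(log-effect and se multiplied by `target/source`) — per 10 cm throughout
the analyses, matching the convention that ~10 cm approximates the
interquartile height range.

## Meta-analysis

Fixed-effect pooling uses weights `1/se_i^2`; the random-effects model adds
a between-study variance `tau^2` estimated by REML (Fisher scoring on the
restricted log-likelihood, step-halving when a step would decrease it,
tolerance 1e-8, floored at 0, DerSimonian–Laird start). Confidence
intervals are Wald normal limits on the log scale — the historical software
default for this literature — with a Knapp–Hartung flag available.
Heterogeneity is reported as Cochran's Q with a chi-square p-value and
`I^2 = max(0, (Q - df)/Q)`. Subgroup homogeneity uses the between-group Q
on pooled subgroup estimates. Studies contributing several strata rows are
treated as independent estimates. All p-values are two-sided.

## Publication-bias tests

Begg–Mazumdar: Kendall rank correlation between the fixed-effect
standardized deviates `u_i = (b_i - b_FE)/sqrt(se_i^2 - se_FE^2)` and the
variances, normal approximation with continuity correction (|P − Q|
reduced by 1). Studies whose variance does not exceed the pooled variance
fall back to the uncorrected variance with a logged warning. An exact
permutation mode (k ≤ 8) enumerates the null of P − Q; it is used as the
small-sample reference in the tests. The normal version is conservative at
small k (calibration band 3–6% at nominal 5% in our checks).

Egger: unweighted OLS of `b_i/se_i` on `1/se_i` (the classical form); the
intercept's t-test on k − 2 df is the asymmetry test. The weighted variant
is out of scope.

## Two-sample Mendelian randomization

**Harmonization.** SNPs are matched on identifier; swapped effect/other
alleles flip the outcome beta (and complement the frequency); strand flips
are reconciled by complementing; palindromic (A/T, C/G) SNPs are dropped by
default, or oriented by allele frequency when both frequencies are farther
than 0.08 from 0.5 (`palindromic="freq"`). Imputation quality below the
threshold (default 0.3, strictly less-than; 0.7 supported for consortia
using that cutoff) drops the SNP. Every drop is counted and logged with a
reason code.

**IVW.** Implemented exactly as the weighted ratio formula above. The
formula ignores exposure-side sampling noise (`se_x` is carried for
diagnostics only), the standard strong-instrument approximation. Its cost
is a small regression-dilution attenuation: at the default instrument scale
(400+ SNPs, r² = 0.16, exposure n ≈ 253k) the attenuation is about 2–3% of
the causal effect — visible only at very high replicate counts and well
inside the Monte-Carlo bands used in the tests, but worth remembering when
effects are large. The fixed-effect (non-overdispersed) standard error is
used, matching the estimator's definition.

**MR-Egger.** Weighted regression with a free intercept after orienting
every SNP to `X_g >= 0` (without a fixed orientation the intercept is not
identifiable as an average pleiotropic effect). Standard errors use the
estimated residual scale with t(n−2) inference, matching a plain weighted
least-squares fit; no lower floor is applied to the scale.

**Power.** Two-sided normal approximation for a case-control outcome:
`power = Phi(b - z_{1-a/2}) + Phi(-b - z_{1-a/2})` with
`b = sqrt(N r2 phi(1-phi)) |log OR|`, `phi` the case fraction and OR per SD
of the exposure. The two-sided form (rather than the upper-tail term alone)
is required for the boundary identity `power(OR=1) = alpha`. At 14,160
cases / 12,724 controls, r² = 0.16 and OR = 1.09 it gives 80.6%, and it
tracks simulated IVW rejection rates within 2 percentage points in the
suite's empirical check.

## Synthetic-data generators

The generators produce inputs with exactly the structure the estimators
assume, so recovery and calibration tests are interpretable.

* **MR tables** (`simulate_mr_summary`): allele frequencies uniform on
  (0.05, 0.5); true per-allele effects oriented to the height-increasing
  allele, floored at the discovery-significance threshold
  (`min_instrument_z = 5.45`, the z for p = 5e-8) and scaled so the
  instrument explains exactly `r2_target` of height variance
  (default 0.16 across 423 SNPs; a 168-SNP/10% configuration mirrors the
  sex-stratified instrument). The significance floor matters: instruments
  are genome-wide significant by construction, and without the floor
  sign-orientation of near-zero effects under sampling noise would reverse
  those SNPs' pleiotropic effects and spuriously bias MR-Egger. Outcome
  standard errors use the balanced logistic approximation
  `sqrt([1/(2p(1-p))](1/n_cases + 1/n_controls))`; pleiotropic effects are
  Normal(mean, sd²), independent of instrument strength (InSIDE) unless
  `pleiotropy_corr` is set. Exposure SD defaults to 7 cm (a typical
  within-sex adult SD; the per-10-cm standardization never depends on it
  when exposure betas are per cm).
* **Study collections** (`simulate_study_collection`): study effects
  Normal(true_beta, tau²) plus Normal noise at per-study SEs drawn uniform
  from `se_range`. Publication selection is *directional*: a significantly
  positive study is always published, anything else with probability
  `selection_prob`. (Suppressing only two-sided-nonsignificant studies
  keeps significant studies of both signs and produces no funnel asymmetry
  under a null effect, so it cannot serve as a positive control.)
* **Cohorts** (`simulate_cohort_study`): normal heights, log-linear risk
  `baseline_risk * exp(beta_per_cm (h - mean))` (an RR model, since the
  meta-analysis pools RRs), empirical-quantile categories, category mean
  heights as scores, Woolf CIs. Configs whose risk exceeds 1 within ±4 SD
  are rejected.

All generators are bit-reproducible from `seed`; replicate k of an
experiment uses `seed + k`.

**What the generators do not emulate:** linkage disequilibrium between
instrument SNPs (the real instrument was pruned to uncorrelated variants),
population stratification, winner's-curse inflation of discovery effect
sizes, covariate-adjusted (rather than crude) category RRs, and overlap of
exposure/outcome samples. Passing tests therefore show the estimators are
correct under their stated assumptions, not that those assumptions hold in
any particular real data set.

## Problem sizes

The test suite uses 5,000 replicates for type-I calibration (Cochran's Q,
Egger, IVW null, Begg), 1,000 for IVW coverage, 500 for Egger/trend
recovery and 2,000 for REML recovery (k = 20 studies). The acceptance
script reports Monte-Carlo summaries at 200–1,000 replicates, sized to make
each reported value stable to well within its comparison tolerance while
keeping a full run in the tens of seconds; cohort experiments use 200,000
subjects (quintiles, baseline risk 5%).

## Known limitations

* The IVW/Egger estimators inherit the printed formulas' neglect of
  exposure-side noise (attenuation ~2–3% at the default instrument; larger
  for weaker instruments).
* REML τ² at small k is noticeably variable; the recovery guarantee is
  about the mean over replicates, not single-study-set estimates.
* The Begg normal approximation is conservative below k ≈ 20; use the
  exact mode for very small collections.
* The GL reconstruction requires internally consistent published numbers;
  inconsistent RR/count combinations surface as non-positive-definite
  covariances rather than silently wrong trends.
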