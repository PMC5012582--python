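# trendmr

Analytic machinery for estimating the association between adult height and
cancer risk, combining two complementary designs:

1. **Dose-response meta-analysis of prospective studies.** Published cohort
   studies usually report relative risks across height *quantiles* against a
   shared reference category. `trendmr` converts each such table into a
   single log-linear trend per 10 cm (Greenland–Longnecker pseudo-count
   reconstruction + generalized least squares), then pools study-level
   trends by inverse-variance weighting (fixed effect and REML random
   effects), with Cochran's Q / I² heterogeneity statistics, subgroup
   homogeneity tests, and Begg / Egger funnel-asymmetry diagnostics.
2. **Two-sample summary-statistic Mendelian randomization.** Height-associated
   SNPs from an exposure GWAS are used as instrumental variables against a
   case-control cancer GWAS. After allele harmonization the causal log-OR is
   estimated by the inverse-variance-weighted (IVW) estimator and probed for
   directional pleiotropy with MR-Egger regression; analytic power for
   case-control outcomes is included.

The package is aimed at epidemiologists and statistical geneticists who want
these estimators as tested, composable functions. All analyses run on
synthetic inputs produced by the built-in generators, which emulate the
structure of the real inputs (a 423-SNP instrument explaining 16% of height
variance; collections of per-10-cm study estimates; cohort quantile tables),
so every stage is testable without external data.

## Core estimators

With per-SNP exposure effects $X_g$, outcome effects $Y_g$ and outcome
standard errors $\sigma_{Y_g}$:

$$\hat\beta_{IVW} = \frac{\sum_g X_g Y_g \sigma_{Y_g}^{-2}}{\sum_g X_g^2 \sigma_{Y_g}^{-2}},
\qquad se(\hat\beta_{IVW}) = \Big(\sum_g X_g^2 \sigma_{Y_g}^{-2}\Big)^{-1/2}.$$

MR-Egger fits $Y_g = \beta_0 + \beta_1 X_g$ by weighted least squares
(weights $\sigma_{Y_g}^{-2}$, SNPs oriented so $X_g \ge 0$): $\beta_0$
estimates the average directional pleiotropic effect, $\beta_1$ the causal
effect under the InSIDE assumption.

For a categorical study with adjusted log relative risks $y_i$ at exposure
scores $x_i$ (relative to the reference category) and pseudo-count
covariance $C$, the trend is
$\hat\beta = (x^\top C^{-1} y)/(x^\top C^{-1} x)$ with
$se = (x^\top C^{-1} x)^{-1/2}$. Meta-analytic pooling uses weights
$w_i = 1/(se_i^2 + \hat\tau^2_{REML})$.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on synthetic
inputs written to `results/data/` (seed 1). `05_mendelian_randomization.py`
harmonizes a 423-SNP height instrument (true causal OR 1.58 per 10 cm)
against a colorectal-cancer outcome panel missing 77 of the SNPs:

```
instrument: 346 SNPs retained of 423 (77 absent from outcome)
IVW: OR per 10 cm = 1.72 (1.48, 2.00), p = 2.49e-12
MR-Egger: OR per 10 cm = 1.53 (1.13, 2.07); intercept = 0.0031, p = 0.387
IVW without 36 pleiotropic SNPs (310 kept): OR per 10 cm = 1.71 (1.46, 2.00)
analytic power at the prostate sample sizes for OR 1.09: 80.6%
```

The IVW estimate brackets the generating OR of 1.58 within its CI, the
Egger intercept is compatible with no directional pleiotropy (none was
simulated), and removing a pre-specified 36-SNP list barely moves the
estimate. `03_meta_analysis.py` pools 62 simulated study estimates
generated around RR 1.10 per 10 cm with between-study variance 0.01:

```
fixed effect:  RR 1.088 (1.069, 1.108)
random effect: RR 1.097 (1.060, 1.136); tau2 = 0.0078
heterogeneity: Q = 149.3 (df 61), p = 2.3e-09, I2 = 59%
```

The same estimators are available from the command line
(`trendmr simulate|trend|meta|bias|mr`); see `trendmr --help`.

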