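"""Synthetic inputs with the statistical structure the analyses assume.

Three generators:

* :func:`simulate_mr_summary` -- paired exposure/outcome GWAS summary-
  statistic tables for a polygenic height instrument (by default 423
  uncorrelated SNPs jointly explaining 16% of height variance, the scale of
  the large height-GWAS instrument) and a case-control cancer outcome under
  a configurable causal log-OR and directional pleiotropy.
* :func:`simulate_study_collection` -- study-level log-RR estimates with
  between-study heterogeneity and optional small-study selection, for
  exercising pooling and funnel-asymmetry diagnostics.
* :func:`simulate_cohort_study` -- a per-quantile categorical table from an
  individual-level cohort under a log-linear risk model, for exercising the
  trend-conversion pipeline.

All generators are bit-reproducible from their config's seed.  Replicate
``k`` of a Monte-Carlo experiment should use ``seed + k``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .dose_response import CategoricalStudy, QuantileLevel
from .meta import StudyEstimate

# non-palindromic allele pairs; effect allele is the height-increasing allele
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class MRSimConfig:
    """Two-sample MR simulation settings.

    ``causal_beta`` is the causal log-OR of the outcome per cm of height;
    per-SNP direct (pleiotropic) log-OR effects are drawn from
    Normal(``pleiotropy_mean``, ``pleiotropy_sd^2``), independently of the
    height effects unless ``pleiotropy_corr`` is non-zero (an InSIDE
    violation for negative-control tests).

    ``min_instrument_z`` enforces that every SNP would reach the discovery
    threshold in the exposure GWAS (true effect >= z * its standard error),
    as genome-wide-significant instruments do by construction; 5.45 is the
    two-sided z for p = 5e-8.  Set 0 to disable.
    """

    n_snps: int = 423
    r2_target: float = 0.16
    n_exposure: int = 253_288
    n_cases: int = 20_000
    n_controls: int = 20_000
    causal_beta: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_corr: float = 0.0
    exposure_sd_cm: float = 7.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    min_instrument_z: float = 5.45
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.r2_target < 1):
            raise ValueError("r2_target must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if min(self.n_snps, self.n_exposure, self.n_cases, self.n_controls) < 1:
            raise ValueError("all counts and sample sizes must be >= 1")
        if self.exposure_sd_cm <= 0:
            raise ValueError("exposure_sd_cm must be positive")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be non-negative")
        if not (-1 <= self.pleiotropy_corr <= 1):
            raise ValueError("pleiotropy_corr must be in [-1, 1]")


@dataclass
class StudySimConfig:
    """Meta-analysis study-collection simulation settings.

    ``selection_prob`` is the probability that a study with a two-sided
    p > 0.05 is published; 1.0 disables small-study selection.
    """

    n_studies: int = 20
    true_beta: float = 0.0
    tau2: float = 0.0
    se_range: tuple[float, float] = (0.05, 0.3)
    selection_prob: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        lo, hi = self.se_range
        if not (0 < lo <= hi):
            raise ValueError("se_range must be positive")
        if not (0 < self.selection_prob <= 1):
            raise ValueError("selection_prob must be in (0, 1]")


@dataclass
class CohortSimConfig:
    """Individual-level cohort simulation settings (log-linear risk model)."""

    n_subjects: int = 200_000
    mean_height_cm: float = 170.0
    sd_height_cm: float = 7.0
    baseline_risk: float = 0.05
    beta_per_cm: float = 0.0
    n_quantiles: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < self.n_quantiles:
            raise ValueError("n_subjects must be at least n_quantiles")
        if not (0 < self.baseline_risk < 1):
            raise ValueError("baseline_risk must be in (0, 1)")
        if self.n_quantiles < 2:
            raise ValueError("n_quantiles must be >= 2")
        if self.sd_height_cm <= 0:
            raise ValueError("sd_height_cm must be positive")
        # risk must stay a probability over +-4 SD of height
        worst = self.baseline_risk * math.exp(abs(self.beta_per_cm) * 4 * self.sd_height_cm)
        if worst >= 1:
            raise ValueError(
                f"risk model exceeds 1 within +-4 SD (reaches {worst:.3g}); "
                "reduce baseline_risk or beta_per_cm"
            )


def simulate_mr_summary(config: MRSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired exposure and outcome GWAS summary-statistic tables.

    True per-allele height effects are oriented to the height-increasing
    allele and scaled so the instrument explains exactly ``r2_target`` of
    height variance: ``sum 2 p_g (1 - p_g) beta_g^2 = r2 sd^2``.  Reported
    effects add sampling noise with the standard GWAS standard errors; the
    outcome uses the balanced logistic (case-control) approximation
    ``se_Y = sqrt([1/(2p(1-p))] (1/n_cases + 1/n_controls))``.

    The per-SNP truths are attached as ``exposure.attrs["true_beta"]`` and
    ``outcome.attrs["true_alpha"]`` for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    g = config.n_snps
    p = rng.uniform(*config.maf_range, size=g)
    het = 2 * p * (1 - p)

    se_x = config.exposure_sd_cm * np.sqrt((1 - config.r2_target) / (het * config.n_exposure))

    raw = np.abs(rng.standard_normal(g))  # height-increasing orientation
    scale = 0.0
    if config.r2_target > 0:
        target = config.r2_target * config.exposure_sd_cm ** 2
        # fixed point: floor effects at the discovery threshold, rescale to
        # keep the explained variance exact
        for _ in range(100):
            scale = math.sqrt(target / np.sum(het * raw ** 2))
            floor = config.min_instrument_z * se_x / scale
            lifted = np.maximum(raw, floor)
            if np.allclose(lifted, raw, rtol=0, atol=1e-13):
                break
            raw = lifted
        scale = math.sqrt(target / np.sum(het * raw ** 2))
    beta_true = raw * scale
    x_obs = beta_true + rng.standard_normal(g) * se_x

    eps = rng.standard_normal(g)
    alpha = config.pleiotropy_mean + config.pleiotropy_sd * eps
    if config.pleiotropy_corr != 0 and config.pleiotropy_sd > 0:
        z_beta = (raw - raw.mean()) / raw.std() if raw.std() > 0 else np.zeros(g)
        alpha = (config.pleiotropy_mean
                 + config.pleiotropy_sd * (config.pleiotropy_corr * z_beta
                                           + math.sqrt(1 - config.pleiotropy_corr ** 2) * eps))
    y_true = config.causal_beta * beta_true + alpha
    se_y = np.sqrt((1.0 / het) * (1.0 / config.n_cases + 1.0 / config.n_controls))
    y_obs = y_true + rng.standard_normal(g) * se_y

    pairs = np.asarray(_ALLELE_PAIRS)
    pick = rng.integers(0, len(pairs), size=g)
    rsid = np.array([f"rs{i + 1:06d}" for i in range(g)])
    info = rng.uniform(0.85, 1.0, size=g).round(4)

    def table(beta: np.ndarray, se: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame({
            "snp": rsid,
            "effect_allele": pairs[pick, 0],
            "other_allele": pairs[pick, 1],
            "eaf": p,
            "beta": beta,
            "se": se,
            "pval": 2 * stats.norm.sf(np.abs(beta / se)),
            "info": info,
        })

    exposure = table(x_obs, se_x)
    outcome = table(y_obs, se_y)
    exposure.attrs["true_beta"] = beta_true
    outcome.attrs["true_alpha"] = alpha
    return exposure, outcome


def simulate_study_collection(config: StudySimConfig) -> list[StudyEstimate]:
    """Study-level log-RR estimates with heterogeneity and optional selection."""
    rng = np.random.default_rng(config.seed)
    theta = config.true_beta + math.sqrt(config.tau2) * rng.standard_normal(config.n_studies)
    se = rng.uniform(*config.se_range, size=config.n_studies)
    beta = theta + rng.standard_normal(config.n_studies) * se
    if config.selection_prob < 1.0:
        # directional selection: a significantly *positive* study is always
        # published; anything else only with probability selection_prob
        pvals = 2 * stats.norm.sf(np.abs(beta / se))
        publish = ((pvals <= 0.05) & (beta > 0)) | (
            rng.uniform(size=config.n_studies) < config.selection_prob
        )
    else:
        publish = np.ones(config.n_studies, dtype=bool)
    estimates = [
        StudyEstimate(study_id=f"study_{i + 1:03d}", beta=float(b), se=float(s))
        for i, (b, s, keep) in enumerate(zip(beta, se, publish)) if keep
    ]
    if len(estimates) < 2:
        raise ValueError("selection left fewer than 2 studies; raise selection_prob or n_studies")
    return estimates


def simulate_cohort_study(config: CohortSimConfig) -> CategoricalStudy:
    """A per-quantile categorical study from a simulated cohort.

    Heights are normal; cases occur with probability
    ``baseline_risk * exp(beta_per_cm * (h - mean))`` (log-linear relative
    risk).  Subjects are cut at empirical quantiles; each category reports
    cases, totals, its mean height as the score, and the crude risk ratio
    versus the lowest category with a Woolf-type log CI.
    """
    rng = np.random.default_rng(config.seed)
    h = config.mean_height_cm + config.sd_height_cm * rng.standard_normal(config.n_subjects)
    risk = config.baseline_risk * np.exp(config.beta_per_cm * (h - config.mean_height_cm))
    case = rng.uniform(size=config.n_subjects) < risk

    edges = np.quantile(h, np.linspace(0, 1, config.n_quantiles + 1))
    idx = np.clip(np.searchsorted(edges, h, side="right") - 1, 0, config.n_quantiles - 1)

    levels: list[QuantileLevel] = []
    cases0 = total0 = None
    for q in range(config.n_quantiles):
        sel = idx == q
        n_total = int(sel.sum())
        n_cases = int(case[sel].sum())
        if n_cases == 0 or n_cases == n_total:
            raise ValueError(
                f"category {q} has {'no' if n_cases == 0 else 'only'} cases; "
                "increase n_subjects or adjust baseline_risk"
            )
        if q == 0:
            cases0, total0 = n_cases, n_total
        risk_q = n_cases / n_total
        rr = risk_q / (cases0 / total0)
        se_log = math.sqrt(1 / n_cases - 1 / n_total + 1 / cases0 - 1 / total0)
        levels.append(QuantileLevel(
            rr=rr if q > 0 else 1.0,
            n_cases=n_cases,
            n_total=n_total,
            lower_cm=None if q == 0 else float(edges[q]),
            upper_cm=None if q == config.n_quantiles - 1 else float(edges[q + 1]),
            score_cm=float(h[sel].mean()),
            ci_low=None if q == 0 else rr * math.exp(-1.959963984540054 * se_log),
            ci_high=None if q == 0 else rr * math.exp(1.959963984540054 * se_log),
            is_reference=q == 0,
        ))
    return CategoricalStudy(
        study_id=f"cohort_seed{config.seed}",
        design="cumulative_incidence",
        levels=levels,
    )


def replicate(config, k: int):
    """Config for Monte-Carlo replicate ``k`` (seed offset by ``k``)."""
    return replace(config, seed=config.seed + k)
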