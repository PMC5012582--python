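"""Inverse-variance-weighted meta-analysis of per-10-cm log relative risks.

Fixed-effect pooling weights each study by its inverse squared standard
error; the random-effects model adds a between-study variance ``tau^2``
estimated by restricted maximum likelihood (Fisher scoring with
step-halving, floored at zero).  Heterogeneity is summarized by Cochran's
Q, its chi-square p-value, and I^2 = max(0, (Q - df)/Q).  Confidence
intervals are Wald normal limits on the log scale (the classical software
default; Knapp-Hartung adjustment is available behind a flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

Z975 = 1.959963984540054


@dataclass
class StudyEstimate:
    """One study's log relative risk per 10 cm of height, with strata labels."""

    study_id: str
    beta: float
    se: float
    strata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.study_id}: beta must be finite")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValueError(f"{self.study_id}: se must be positive and finite")


@dataclass
class MetaResult:
    """Pooled effect with heterogeneity summaries (CI on the RR scale)."""

    model: Literal["fixed", "random"]
    beta: float
    se: float
    ci_low: float
    ci_high: float
    k: int
    Q: float
    df: int
    p_Q: float
    tau2: float
    i2: float

    @property
    def rr(self) -> float:
        return math.exp(self.beta)

    @property
    def p(self) -> float:
        return 2 * stats.norm.sf(abs(self.beta / self.se))


def _arrays(estimates: Sequence[StudyEstimate]) -> tuple[np.ndarray, np.ndarray]:
    beta = np.asarray([e.beta for e in estimates], dtype=float)
    se = np.asarray([e.se for e in estimates], dtype=float)
    return beta, se


def _heterogeneity(beta: np.ndarray, se: np.ndarray) -> tuple[float, int, float, float]:
    """(Q, df, p, I^2) from fixed-effect weights; NaNs for a single study."""
    k = len(beta)
    if k < 2:
        return math.nan, 0, math.nan, 0.0
    w = se ** -2
    mu = float(np.sum(w * beta) / np.sum(w))
    q = float(np.sum(w * (beta - mu) ** 2))
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return q, df, p, i2


def fixed_effect_meta(estimates: Sequence[StudyEstimate]) -> MetaResult:
    """Inverse-variance fixed-effect pooled estimate."""
    if len(estimates) == 0:
        raise ValueError("no estimates to pool")
    beta, se = _arrays(estimates)
    w = se ** -2
    mu = float(np.sum(w * beta) / np.sum(w))
    se_pool = float(np.sum(w) ** -0.5)
    q, df, p_q, i2 = _heterogeneity(beta, se)
    return MetaResult(
        model="fixed", beta=mu, se=se_pool,
        ci_low=math.exp(mu - Z975 * se_pool), ci_high=math.exp(mu + Z975 * se_pool),
        k=len(estimates), Q=q, df=df, p_Q=p_q, tau2=0.0, i2=i2,
    )


def cochran_q(estimates: Sequence[StudyEstimate]) -> tuple[float, int, float]:
    """Cochran's homogeneity test: Q statistic, degrees of freedom, p-value."""
    if len(estimates) < 2:
        raise ValueError("Cochran's Q requires at least 2 estimates")
    beta, se = _arrays(estimates)
    q, df, p, _ = _heterogeneity(beta, se)
    return q, df, p


def _reml_loglik(tau2: float, beta: np.ndarray, v0: np.ndarray) -> float:
    v = v0 + tau2
    w = 1.0 / v
    mu = np.sum(w * beta) / np.sum(w)
    return float(
        -0.5 * np.sum(np.log(v)) - 0.5 * math.log(np.sum(w))
        - 0.5 * np.sum(w * (beta - mu) ** 2)
    )


def reml_tau2(
    estimates: Sequence[StudyEstimate], tol: float = 1e-8, max_iter: int = 100
) -> float:
    """Restricted-maximum-likelihood between-study variance.

    Fisher scoring on tau^2 with step-halving whenever a step would lower
    the restricted log-likelihood or leave tau^2 < 0; the estimate is
    floored at zero (boundary solutions are legitimate).
    """
    if len(estimates) < 2:
        raise ValueError("tau^2 estimation requires at least 2 estimates")
    beta, se = _arrays(estimates)
    v0 = se ** 2
    k = len(beta)

    # DerSimonian-Laird start, floored at zero
    w = 1.0 / v0
    mu = np.sum(w * beta) / np.sum(w)
    q = np.sum(w * (beta - mu) ** 2)
    c = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    tau2 = max(0.0, float((q - (k - 1)) / c)) if c > 0 else 0.0

    for _ in range(max_iter):
        v = v0 + tau2
        w = 1.0 / v
        sw, sw2, sw3 = np.sum(w), np.sum(w ** 2), np.sum(w ** 3)
        mu = np.sum(w * beta) / sw
        r = beta - mu
        # REML score and expected information for tau^2
        score = 0.5 * (np.sum(w ** 2 * r ** 2) - (sw - sw2 / sw))
        info = 0.5 * (sw2 - 2 * sw3 / sw + (sw2 / sw) ** 2)
        if info <= 0:
            break
        step = score / info
        if tau2 == 0.0 and score <= 0:
            return 0.0  # boundary optimum
        ll_old = _reml_loglik(tau2, beta, v0)
        new = tau2 + step
        halvings = 0
        while (new < 0 or _reml_loglik(new, beta, v0) < ll_old - 1e-12) and halvings < 60:
            step /= 2
            new = tau2 + step
            halvings += 1
        new = max(0.0, new)
        if abs(new - tau2) < tol:
            return float(new)
        tau2 = float(new)
    raise ValueError(f"REML did not converge within {max_iter} iterations (last tau2={tau2:.6g})")


def random_effects_meta(
    estimates: Sequence[StudyEstimate], knapp_hartung: bool = False
) -> MetaResult:
    """REML random-effects pooled estimate.

    Heterogeneity statistics (Q, I^2) are reported from fixed-effect weights,
    as is conventional.  ``knapp_hartung=True`` swaps the Wald normal CI for
    the Knapp-Hartung t-based interval.
    """
    if len(estimates) < 2:
        raise ValueError("random-effects pooling requires at least 2 estimates")
    beta, se = _arrays(estimates)
    tau2 = reml_tau2(estimates)
    w = 1.0 / (se ** 2 + tau2)
    mu = float(np.sum(w * beta) / np.sum(w))
    se_pool = float(np.sum(w) ** -0.5)
    q, df, p_q, i2 = _heterogeneity(beta, se)
    if knapp_hartung:
        s2 = float(np.sum(w * (beta - mu) ** 2) / (len(beta) - 1))
        se_kh = se_pool * math.sqrt(max(s2, 1.0)) if s2 > 0 else se_pool
        crit = stats.t.ppf(0.975, len(beta) - 1)
        lo, hi = mu - crit * se_kh, mu + crit * se_kh
        se_pool = se_kh
    else:
        lo, hi = mu - Z975 * se_pool, mu + Z975 * se_pool
    return MetaResult(
        model="random", beta=mu, se=se_pool,
        ci_low=math.exp(lo), ci_high=math.exp(hi),
        k=len(estimates), Q=q, df=df, p_Q=p_q, tau2=tau2, i2=i2,
    )


def subgroup_homogeneity(
    subgroup_results: Sequence[tuple[float, float]]
) -> tuple[float, int, float]:
    """Between-subgroup homogeneity test on pooled summary estimates.

    Accepts ``(beta, se)`` pairs or any objects exposing ``.beta``/``.se``
    (MetaResult, MRResult).  Q_between is the inverse-variance weighted sum
    of squared deviations of subgroup estimates from their common IVW mean.
    """
    pairs = []
    for r in subgroup_results:
        if hasattr(r, "beta"):
            pairs.append((float(r.beta), float(r.se)))
        else:
            b, s = r
            pairs.append((float(b), float(s)))
    if len(pairs) < 2:
        raise ValueError("need at least 2 subgroup estimates")
    beta = np.asarray([p[0] for p in pairs])
    se = np.asarray([p[1] for p in pairs])
    w = se ** -2
    mu = np.sum(w * beta) / np.sum(w)
    q = float(np.sum(w * (beta - mu) ** 2))
    df = len(pairs) - 1
    return q, df, float(stats.chi2.sf(q, df))


def forest_table(
    estimates: Sequence[StudyEstimate],
    model: Literal["fixed", "random"] = "random",
    by: str | None = None,
) -> pd.DataFrame:
    """Plot-ready forest table: one row per study plus pooled summary rows.

    With ``by`` set to a stratum key, studies are grouped into blocks by that
    label and each block gets its own summary row; an overall summary row is
    always appended.  ``weight_pct`` are the model's normalized weights and
    sum to 100 within each pooled block.
    """

    def pool(block: Sequence[StudyEstimate]) -> MetaResult:
        if model == "random" and len(block) >= 2:
            return random_effects_meta(block)
        return fixed_effect_meta(block)

    def block_rows(label: str, block: Sequence[StudyEstimate]) -> list[dict]:
        res = pool(block)
        w = np.asarray([1.0 / (e.se ** 2 + res.tau2) for e in block])
        w = 100.0 * w / w.sum()
        rows = [
            {
                "block": label, "row_type": "study", "study_id": e.study_id,
                "rr": math.exp(e.beta),
                "ci_low": math.exp(e.beta - Z975 * e.se),
                "ci_high": math.exp(e.beta + Z975 * e.se),
                "weight_pct": wi,
            }
            for e, wi in zip(block, w)
        ]
        rows.append({
            "block": label, "row_type": "summary", "study_id": f"{label} ({res.model})",
            "rr": res.rr, "ci_low": res.ci_low, "ci_high": res.ci_high,
            "weight_pct": 100.0,
        })
        return rows

    rows: list[dict] = []
    if by is not None:
        labels = sorted({e.strata.get(by, "unspecified") for e in estimates})
        for label in labels:
            block = [e for e in estimates if e.strata.get(by, "unspecified") == label]
            rows.extend(block_rows(f"{by}={label}", block))
    rows.extend(block_rows("overall", list(estimates)))
    return pd.DataFrame(rows)
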