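"""Funnel-plot data and small-study/publication-bias tests.

Begg-Mazumdar rank correlation: the fixed-effect-standardized study
deviates are rank-correlated (Kendall) with the study variances; under no
small-study effect the correlation is null.  The normal approximation with
continuity correction is the default; an exact permutation p-value is
available for small study sets.

Egger regression: the standardized effect ``beta_i / se_i`` is regressed on
precision ``1 / se_i`` by unweighted OLS (the classical form); a non-zero
intercept indicates funnel asymmetry, tested with a t statistic on k - 2
degrees of freedom.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .meta import MetaResult, StudyEstimate, Z975, fixed_effect_meta

logger = logging.getLogger("trendmr.bias")


@dataclass
class BiasTestResult:
    """Outcome of a funnel-asymmetry test."""

    test: Literal["begg", "egger"]
    statistic: float
    p: float
    intercept: float | None = None
    se_intercept: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def funnel_table(
    estimates: Sequence[StudyEstimate], pooled: MetaResult, n_grid: int = 50
) -> pd.DataFrame:
    """Per-study (beta, se) points plus pseudo-95%-limit curves.

    Limit rows trace ``pooled.beta +- 1.96 * se`` over an se grid from 0 to
    the largest observed standard error, so the funnel converges to the
    pooled estimate at se = 0.
    """
    rows = [
        {"kind": "study", "study_id": e.study_id, "beta": e.beta, "se": e.se,
         "lower": math.nan, "upper": math.nan}
        for e in estimates
    ]
    for s in np.linspace(0.0, max(e.se for e in estimates), n_grid):
        rows.append({
            "kind": "limit", "study_id": "", "beta": pooled.beta, "se": float(s),
            "lower": pooled.beta - Z975 * s, "upper": pooled.beta + Z975 * s,
        })
    return pd.DataFrame(rows)


def _kendall_pq(u: np.ndarray, v: np.ndarray) -> int:
    """P - Q: concordant minus discordant pairs between u and v."""
    du = np.sign(u[:, None] - u[None, :])
    dv = np.sign(v[:, None] - v[None, :])
    return int(np.sum(np.triu(du * dv, k=1)))


def begg_test(
    estimates: Sequence[StudyEstimate],
    method: Literal["normal", "exact"] = "normal",
) -> BiasTestResult:
    """Begg-Mazumdar adjusted rank-correlation test for funnel asymmetry.

    Deviates ``u_i = (beta_i - beta_FE) / sqrt(se_i^2 - se_FE^2)`` are
    correlated with the variances ``se_i^2``.  ``method="normal"`` applies
    the z approximation with continuity correction (|P - Q| reduced by 1);
    ``method="exact"`` enumerates the permutation null of P - Q (k <= 8).
    """
    k = len(estimates)
    if k < 3:
        raise ValueError("Begg's test requires at least 3 studies")
    beta, se = np.asarray([e.beta for e in estimates]), np.asarray([e.se for e in estimates])
    pooled = fixed_effect_meta(estimates)
    var_dev = se ** 2 - pooled.se ** 2
    bad = var_dev <= 0
    if np.any(bad):
        logger.warning(
            "%d stud(ies) with variance <= pooled variance; using uncorrected variance",
            int(bad.sum()),
        )
        var_dev[bad] = se[bad] ** 2
    u = (beta - pooled.beta) / np.sqrt(var_dev)
    v = se ** 2
    pq = _kendall_pq(u, v)

    if method == "exact":
        if k > 8:
            raise ValueError("exact permutation enumeration limited to k <= 8")
        null = np.fromiter(
            (_kendall_pq(u[list(perm)], v) for perm in itertools.permutations(range(k))),
            dtype=float,
        )
        p = float(np.mean(np.abs(null) >= abs(pq)))
        return BiasTestResult(test="begg", statistic=float(pq), p=p)

    denom = math.sqrt(k * (k - 1) * (2 * k + 5) / 18)
    z = math.copysign(max(abs(pq) - 1, 0), pq) / denom
    p = 2 * stats.norm.sf(abs(z))
    return BiasTestResult(test="begg", statistic=float(z), p=float(p))


def egger_bias_test(estimates: Sequence[StudyEstimate]) -> BiasTestResult:
    """Egger's regression test: OLS of beta_i/se_i on 1/se_i with intercept."""
    k = len(estimates)
    if k < 3:
        raise ValueError("Egger's test requires at least 3 studies")
    beta, se = np.asarray([e.beta for e in estimates]), np.asarray([e.se for e in estimates])
    if np.allclose(se, se[0]):
        raise ValueError("all standard errors equal; precision has no variance")
    y = beta / se
    x = 1.0 / se
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    slope = float(np.sum((x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = y - intercept - slope * x
    s2 = float(np.sum(resid ** 2) / (k - 2))
    se_int = math.sqrt(s2 * (1.0 / k + xbar ** 2 / sxx))
    t = intercept / se_int
    p = 2 * stats.t.sf(abs(t), k - 2)
    return BiasTestResult(
        test="egger", statistic=float(t), p=float(p),
        intercept=intercept, se_intercept=se_int,
    )
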