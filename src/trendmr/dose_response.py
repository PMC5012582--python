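"""Convert per-quantile relative risks into a linear log-RR trend.

Published cohort studies often report relative risks for quantiles of an
exposure (here: categories of adult height) against a shared reference
category.  Because every non-reference category is compared with the same
reference group, the category-specific log relative risks are correlated,
and a naive weighted regression of log-RR on exposure score understates the
trend's precision.

The Greenland-Longnecker approach reconstructs a table of *pseudo-counts*
that is exactly consistent with the published adjusted RRs and the observed
margins (cases and denominators per category).  From that table the full
covariance matrix of the non-reference log-RRs follows from standard
Woolf-type formulas, and the per-unit trend is estimated by generalized
least squares through the reference point.

The module implements:

* :func:`assign_scores` -- exposure scores per category, with the
  half-adjacent-width rule for open-ended extreme categories,
* :func:`gl_pseudo_counts` -- Newton solution of the margin equations,
* :func:`gl_covariance` -- design-specific covariance of log-RRs,
* :func:`gls_trend` -- the GLS slope and standard error,
* :func:`rescale_estimate` -- unit conversion (e.g. per cm -> per 10 cm),
* :func:`trend_from_study` -- the full pipeline with an independence
  fallback when per-category counts are unavailable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

logger = logging.getLogger("trendmr.dose_response")

Design = Literal["incidence_rate", "cumulative_incidence", "case_control"]

#: divisor converting a 95% CI width on the log scale into a standard error
CI_TO_SE_DIVISOR = 2 * 1.959963984540054


@dataclass
class QuantileLevel:
    """One exposure category of a published categorical study.

    ``rr`` is the study's *adjusted* relative risk for this category versus
    the reference category (1.0 at the reference itself).  Bounds may be
    ``None`` for open-ended extreme categories.
    """

    rr: float
    n_cases: float | None = None
    n_total: float | None = None
    person_time: float | None = None
    lower_cm: float | None = None
    upper_cm: float | None = None
    score_cm: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    is_reference: bool = False

    def ci_se(self) -> float:
        """Standard error of log RR implied by the published 95% CI."""
        if self.ci_low is None or self.ci_high is None:
            raise ValueError("level has no confidence interval")
        half_hi = math.log(self.ci_high / self.rr)
        half_lo = math.log(self.rr / self.ci_low)
        if half_lo <= 0 or half_hi <= 0:
            raise ValueError(f"confidence interval does not bracket rr={self.rr}")
        if max(half_hi / half_lo, half_lo / half_hi) > 1.1:
            logger.warning(
                "asymmetric CI (%.4g, %.4g) around rr=%.4g; using average half-width",
                self.ci_low, self.ci_high, self.rr,
            )
        return (half_hi + half_lo) / CI_TO_SE_DIVISOR


@dataclass
class CategoricalStudy:
    """Ordered exposure categories from one study, plus strata labels."""

    study_id: str
    design: Design
    levels: list[QuantileLevel]
    strata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"{self.study_id}: need >= 2 levels")
        n_ref = sum(lv.is_reference for lv in self.levels)
        if n_ref != 1:
            raise ValueError(f"{self.study_id}: exactly one reference level required, got {n_ref}")
        ref = self.reference
        if abs(ref.rr - 1.0) > 1e-12:
            raise ValueError(f"{self.study_id}: reference level must have rr = 1")
        for lv in self.levels:
            if not lv.is_reference and lv.ci_low is not None and lv.ci_high is not None:
                if not (lv.ci_low < lv.rr < lv.ci_high):
                    raise ValueError(
                        f"{self.study_id}: CI ({lv.ci_low}, {lv.ci_high}) does not bracket rr={lv.rr}"
                    )
        bounds = [b for lv in self.levels for b in (lv.lower_cm, lv.upper_cm) if b is not None]
        if any(b2 < b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError(f"{self.study_id}: level bounds must be non-decreasing")

    @property
    def reference(self) -> QuantileLevel:
        return next(lv for lv in self.levels if lv.is_reference)

    @property
    def reference_index(self) -> int:
        return next(i for i, lv in enumerate(self.levels) if lv.is_reference)

    def denominators(self) -> np.ndarray:
        """Per-level totals (person-time for rate data, subjects otherwise)."""
        if self.design == "incidence_rate":
            vals = [lv.person_time for lv in self.levels]
            kind = "person_time"
        else:
            vals = [lv.n_total for lv in self.levels]
            kind = "n_total"
        if any(v is None for v in vals):
            raise ValueError(f"{self.study_id}: {kind} required for every level")
        return np.asarray(vals, dtype=float)

    def has_counts(self) -> bool:
        try:
            self.denominators()
        except ValueError:
            return False
        return all(lv.n_cases is not None for lv in self.levels)


@dataclass
class TrendEstimate:
    """A linear log-RR trend per ``unit_cm`` of exposure."""

    beta: float
    se: float
    unit_cm: float = 1.0
    n_levels_used: int = 0
    method: Literal["gl", "independence_fallback"] = "gl"

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be positive")

    @property
    def rr(self) -> float:
        return math.exp(self.beta)

    @property
    def ci(self) -> tuple[float, float]:
        half = 1.959963984540054 * self.se
        return math.exp(self.beta - half), math.exp(self.beta + half)


def assign_scores(
    study: CategoricalStudy, method: Literal["given", "midpoint"] = "midpoint"
) -> CategoricalStudy:
    """Fill in an exposure score for every category.

    Supplied scores (category means/medians reported by the study) are used
    verbatim.  With ``method="midpoint"`` missing scores for closed intervals
    are midpoints, and an open-ended extreme interval receives the adjacent
    closed interval's boundary plus/minus half its width (upper-open:
    lower bound + w/2; lower-open: upper bound - w/2).
    """
    levels = [replace(lv) for lv in study.levels]
    if method == "given":
        missing = [i for i, lv in enumerate(levels) if lv.score_cm is None]
        if missing:
            raise ValueError(f"{study.study_id}: no supplied score at level(s) {missing}")
        return replace(study, levels=levels)

    def width(lv: QuantileLevel) -> float | None:
        if lv.lower_cm is None or lv.upper_cm is None:
            return None
        return lv.upper_cm - lv.lower_cm

    for i, lv in enumerate(levels):
        if lv.score_cm is not None:
            continue
        if lv.lower_cm is not None and lv.upper_cm is not None:
            lv.score_cm = (lv.lower_cm + lv.upper_cm) / 2
        elif lv.upper_cm is None and lv.lower_cm is not None:
            if i == 0 or (w := width(levels[i - 1])) is None:
                raise ValueError(
                    f"{study.study_id}: open interval at level {i} adjacent to another "
                    "open interval; no width available"
                )
            lv.score_cm = lv.lower_cm + w / 2
        elif lv.lower_cm is None and lv.upper_cm is not None:
            if i == len(levels) - 1 or (w := width(levels[i + 1])) is None:
                raise ValueError(
                    f"{study.study_id}: open interval at level {i} adjacent to another "
                    "open interval; no width available"
                )
            lv.score_cm = lv.upper_cm - w / 2
        else:
            raise ValueError(f"{study.study_id}: level {i} has no bounds and no score")
    return replace(study, levels=levels)


@dataclass
class PseudoCounts:
    """Fitted pseudo-cases (and complements) consistent with adjusted RRs."""

    cases: np.ndarray            # pseudo cases A_i, one per level (study order)
    denominators: np.ndarray     # N_i (subjects) or T_i (person-time)
    design: Design
    n_iterations: int = 0

    @property
    def noncases(self) -> np.ndarray:
        if self.design == "incidence_rate":
            raise ValueError("rate data has no non-case counts")
        return self.denominators - self.cases


def _cases_given_reference(
    a_ref: float, rr: np.ndarray, denom: np.ndarray, ref: int, design: Design
) -> np.ndarray:
    """Pseudo cases at every level implied by the reference-cell count."""
    if design in ("incidence_rate", "cumulative_incidence"):
        return a_ref * rr * denom / denom[ref]
    # case-control: rr is an odds ratio vs reference
    odds0 = a_ref / (denom[ref] - a_ref)
    c = rr * odds0
    return denom * c / (1.0 + c)


def gl_pseudo_counts(
    study: CategoricalStudy, tol: float = 1e-10, max_iter: int = 100
) -> PseudoCounts:
    """Solve for pseudo-counts matching adjusted RRs and observed margins.

    Newton iteration on the reference-cell pseudo count ``A_0``: given
    ``A_0``, the adjusted RRs determine every other pseudo count; ``A_0`` is
    adjusted until the total number of cases matches the observed total.
    Steps are damped whenever they would push a pseudo count out of range.
    """
    if not study.has_counts():
        raise ValueError(f"{study.study_id}: cases and denominators required for every level")
    denom = study.denominators()
    cases = np.asarray([lv.n_cases for lv in study.levels], dtype=float)
    rr = np.asarray([lv.rr for lv in study.levels], dtype=float)
    ref = study.reference_index
    total_cases = cases.sum()

    a_ref = float(cases[ref])
    upper = denom[ref] if study.design != "incidence_rate" else math.inf
    a_ref = min(max(a_ref, 1e-8), upper - 1e-8 if math.isfinite(upper) else a_ref)

    h = 1e-6
    for it in range(1, max_iter + 1):
        a = _cases_given_reference(a_ref, rr, denom, ref, study.design)
        g = a.sum() - total_cases
        if abs(g) < tol:
            if np.any(a <= 0):
                bad = int(np.argmin(a))
                raise ValueError(
                    f"{study.study_id}: non-positive fitted pseudo-count at level {bad}"
                )
            return PseudoCounts(a, denom, study.design, n_iterations=it)
        step_h = h * max(1.0, abs(a_ref))
        g_hi = _cases_given_reference(a_ref + step_h, rr, denom, ref, study.design).sum() - total_cases
        dg = (g_hi - g) / step_h
        if dg == 0:
            raise ValueError(f"{study.study_id}: Newton iteration stalled (zero derivative)")
        step = -g / dg
        new = a_ref + step
        # damp steps that would leave the feasible region
        while new <= 0 or new >= upper:
            step /= 2
            new = a_ref + step
            if abs(step) < 1e-14:
                raise ValueError(f"{study.study_id}: Newton step collapsed at boundary")
        a_ref = new
    raise ValueError(
        f"{study.study_id}: pseudo-count iteration did not converge in {max_iter} "
        f"iterations (last reference cell {a_ref:.6g})"
    )


def gl_covariance(study: CategoricalStudy, pseudo: PseudoCounts) -> np.ndarray:
    """Covariance matrix of the non-reference log-RRs from pseudo-counts.

    All non-reference categories share the reference cell, so off-diagonal
    covariances equal the reference cell's variance contribution.
    """
    ref = study.reference_index
    idx = [i for i in range(len(study.levels)) if i != ref]
    a = pseudo.cases
    n = pseudo.denominators
    if study.design == "incidence_rate":
        own = 1.0 / a[idx]
        shared = 1.0 / a[ref]
    elif study.design == "cumulative_incidence":
        own = 1.0 / a[idx] - 1.0 / n[idx]
        shared = 1.0 / a[ref] - 1.0 / n[ref]
    else:  # case_control
        b = pseudo.noncases
        own = 1.0 / a[idx] + 1.0 / b[idx]
        shared = 1.0 / a[ref] + 1.0 / b[ref]
    cov = np.full((len(idx), len(idx)), shared)
    cov[np.diag_indices_from(cov)] = own + shared
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            f"{study.study_id}: covariance not positive definite; "
            "published counts and RRs are inconsistent"
        ) from err
    return cov


def gls_trend(study: CategoricalStudy, cov: np.ndarray | None = None) -> TrendEstimate:
    """GLS slope of log-RR on exposure score, through the reference point.

    With ``x_i = score_i - score_ref`` and ``y_i = log(adjusted RR_i)`` over
    the non-reference levels, ``beta = x'C^-1 y / x'C^-1 x`` and
    ``se = (x'C^-1 x)^-1/2``.  Passing ``cov=None`` selects the independence
    fallback, which weights levels by their published-CI variances and
    ignores the shared-reference correlation.
    """
    ref = study.reference_index
    if any(lv.score_cm is None for lv in study.levels):
        raise ValueError(f"{study.study_id}: scores not assigned; call assign_scores first")
    others = [lv for i, lv in enumerate(study.levels) if i != ref]
    x = np.asarray([lv.score_cm - study.levels[ref].score_cm for lv in others])
    y = np.log([lv.rr for lv in others])
    if np.allclose(x, x[0]) and len(x) > 1 or np.all(x == 0):
        raise ValueError(f"{study.study_id}: no exposure contrast between scores")
    method: Literal["gl", "independence_fallback"]
    if cov is None:
        cov = np.diag([lv.ci_se() ** 2 for lv in others])
        method = "independence_fallback"
    else:
        method = "gl"
    ci_x = np.linalg.solve(cov, x)
    xtcx = float(x @ ci_x)
    beta = float(ci_x @ y) / xtcx
    return TrendEstimate(
        beta=beta,
        se=1.0 / math.sqrt(xtcx),
        unit_cm=1.0,
        n_levels_used=len(study.levels),
        method=method,
    )


def rescale_estimate(estimate: TrendEstimate, target_unit_cm: float) -> TrendEstimate:
    """Re-express a trend per a different exposure increment (e.g. 10 cm)."""
    if estimate.unit_cm is None or estimate.unit_cm <= 0:
        raise ValueError("source unit unknown or non-positive")
    if target_unit_cm <= 0:
        raise ValueError("target unit must be positive")
    factor = target_unit_cm / estimate.unit_cm
    return replace(estimate, beta=estimate.beta * factor, se=estimate.se * factor,
                   unit_cm=target_unit_cm)


def rescale_rr_ci(
    rr: float, ci_low: float, ci_high: float,
    source_unit_cm: float, target_unit_cm: float,
) -> tuple[float, float, float]:
    """Re-express a published RR and CI per a different exposure increment.

    Log effect and log bounds are multiplied by ``target/source`` and
    exponentiated (a 5 cm -> 10 cm conversion squares the RR and bounds).
    """
    if source_unit_cm <= 0 or target_unit_cm <= 0:
        raise ValueError("exposure units must be positive")
    f = target_unit_cm / source_unit_cm
    return rr ** f, ci_low ** f, ci_high ** f


def trend_from_study(
    study: CategoricalStudy,
    scores: Literal["given", "midpoint"] = "midpoint",
    unit_cm: float = 10.0,
) -> TrendEstimate:
    """Full pipeline: scores -> pseudo-counts -> covariance -> GLS -> rescale.

    Falls back to independence weighting (with a warning) when per-category
    counts are not available.
    """
    scored = assign_scores(study, method=scores)
    if scored.has_counts():
        pseudo = gl_pseudo_counts(scored)
        cov = gl_covariance(scored, pseudo)
    else:
        logger.warning(
            "%s: per-level counts unavailable; using independence fallback", study.study_id
        )
        cov = None
    return rescale_estimate(gls_trend(scored, cov), unit_cm)
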