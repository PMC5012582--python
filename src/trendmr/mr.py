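"""Two-sample summary-statistic Mendelian randomization.

Exposure (height) and outcome (cancer case-control) GWAS summary statistics
are harmonized to a common effect-allele orientation, then combined with
the inverse-variance-weighted (IVW) estimator

    beta_IVW = sum(X_g Y_g / s_g^2) / sum(X_g^2 / s_g^2),
    se(beta_IVW) = sqrt(1 / sum(X_g^2 / s_g^2)),

where ``X_g`` is the per-allele height effect, ``Y_g`` the per-allele
log-odds effect on the cancer, and ``s_g`` the outcome standard error.
Exposure-side uncertainty does not enter the estimator (the standard
two-sample approximation for strong instruments); exposure standard errors
are carried for diagnostics only.

MR-Egger regression relaxes the exclusion restriction: a weighted
regression of ``Y_g`` on ``X_g`` with a free intercept, after orienting
every SNP so that ``X_g >= 0``.  The intercept estimates the average
directional pleiotropic effect; the slope is a consistent causal estimate
under the InSIDE assumption (pleiotropic effects independent of instrument
strength).

Also here: imputation-quality filtering, exclusion of pre-specified
pleiotropic variants, per-10-cm standardization of odds ratios, and an
analytic power approximation for case-control outcomes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("trendmr.mr")

Z975 = 1.959963984540054

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SnpRecord:
    """One SNP's association summary (per copy of the effect allele)."""

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float | None = None
    eaf: float | None = None
    info: float | None = None

    def __post_init__(self) -> None:
        self.effect_allele = self.effect_allele.upper()
        self.other_allele = self.other_allele.upper()
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: alleles must be distinct")
        if self.se <= 0:
            raise ValueError(f"{self.rsid}: se must be positive")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"{self.rsid}: eaf must be in (0, 1)")


@dataclass
class HarmonizedInstrument:
    """Aligned per-SNP exposure/outcome effects and bookkeeping counts."""

    rsid: np.ndarray          # SNP identifiers (retained set)
    x: np.ndarray             # exposure betas X_g, per exposure unit
    se_x: np.ndarray          # exposure SEs (diagnostics only)
    y: np.ndarray             # outcome log-odds betas Y_g
    se_y: np.ndarray          # outcome SEs sigma_Yg
    n_input_exposure: int
    n_dropped_missing: int = 0
    n_dropped_info: int = 0
    n_dropped_palindromic: int = 0
    n_dropped_mismatch: int = 0
    exposure_unit: str = "cm"

    def __post_init__(self) -> None:
        lens = {len(self.rsid), len(self.x), len(self.se_x), len(self.y), len(self.se_y)}
        if len(lens) != 1:
            raise ValueError("instrument arrays must have equal length")
        dropped = (self.n_dropped_missing + self.n_dropped_info
                   + self.n_dropped_palindromic + self.n_dropped_mismatch)
        if self.n_input_exposure != self.n_snps + dropped:
            raise ValueError("SNP accounting does not balance")

    @property
    def n_snps(self) -> int:
        return len(self.rsid)

    def subset(self, keep: np.ndarray) -> "HarmonizedInstrument":
        return replace(
            self, rsid=self.rsid[keep], x=self.x[keep], se_x=self.se_x[keep],
            y=self.y[keep], se_y=self.se_y[keep],
            n_input_exposure=int(np.sum(keep)),
            n_dropped_missing=0, n_dropped_info=0,
            n_dropped_palindromic=0, n_dropped_mismatch=0,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp": self.rsid, "x": self.x, "se_x": self.se_x,
            "y": self.y, "se_y": self.se_y,
        })


@dataclass
class MRResult:
    """Causal estimate from summary-statistic MR.

    ``beta``/``se`` are on the instrument's exposure scale (log odds per
    ``exposure unit``); :func:`standardize_or` converts to per 10 cm and
    fills the odds-ratio fields.
    """

    method: Literal["ivw", "egger"]
    beta: float
    se: float
    p: float
    n_snps: int
    exposure_unit_cm: float | None = None
    or_per_10cm: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    intercept: float | None = None
    se_intercept: float | None = None
    p_intercept: float | None = None


def filter_info(records: pd.DataFrame, threshold: float = 0.3) -> pd.DataFrame:
    """Drop SNPs with imputation quality below ``threshold``.

    The boundary is kept (the exclusion rule is strictly ``info < threshold``).
    Tables without an ``info`` column pass unchanged with a warning.  The
    number removed is logged and stored in ``.attrs["n_dropped_info"]``.
    """
    if "info" not in records.columns or records["info"].isna().all():
        logger.warning("no imputation-quality column; info filter skipped")
        out = records.copy()
        out.attrs["n_dropped_info"] = 0
        return out
    keep = ~(records["info"] < threshold)  # NaN info passes
    out = records.loc[keep].copy()
    n_dropped = int((~keep).sum())
    out.attrs["n_dropped_info"] = n_dropped
    if n_dropped:
        logger.info("DROP_INFO removed %d SNP(s) with info < %g", n_dropped, threshold)
    return out


def _is_palindromic(ea: pd.Series, oa: pd.Series) -> pd.Series:
    return oa == ea.map(_COMPLEMENT)


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    info_threshold: float | None = 0.3,
    palindromic: Literal["strict", "freq"] = "strict",
    eaf_threshold: float = 0.08,
    exposure_unit: str = "cm",
) -> HarmonizedInstrument:
    """Align outcome effects to the exposure's effect alleles.

    Rules, applied per SNP matched on rsid:

    * same allele pair, same orientation: keep as is;
    * effect/other swapped: flip the outcome beta's sign, complement eaf;
    * strand-flipped (complementary alleles), possibly swapped: complement,
      then as above;
    * palindromic (A/T or C/G) SNPs: dropped in ``strict`` mode; in ``freq``
      mode oriented by allele frequency when both frequencies are decisive
      (further than ``eaf_threshold`` from 0.5), dropped otherwise;
    * anything irreconcilable is dropped with a logged reason.

    SNPs absent from the outcome table and SNPs below the imputation-quality
    threshold (checked on both tables) are dropped and counted.
    """
    for name, tab in (("exposure", exposure), ("outcome", outcome)):
        if tab["snp"].duplicated().any():
            raise ValueError(f"duplicate rsids in {name} table")
    n_input = len(exposure)

    exp = exposure.copy()
    out = outcome.copy()
    n_info = 0
    if info_threshold is not None:
        exp = filter_info(exp, info_threshold)
        n_info += exp.attrs["n_dropped_info"]
        out_f = filter_info(out, info_threshold)
        # exposure SNPs lost because their outcome row failed the filter
        lost = exp["snp"].isin(out["snp"]) & ~exp["snp"].isin(out_f["snp"])
        n_info += int(lost.sum())
        exp = exp.loc[~lost]
        out = out_f

    merged = exp.merge(out, on="snp", suffixes=("_x", "_y"), how="left")
    missing = merged["beta_y"].isna()
    n_missing = int(missing.sum())
    if n_missing:
        logger.info("DROP_MISSING %d exposure SNP(s) absent from outcome", n_missing)
    m = merged.loc[~missing].copy()

    for col in ("effect_allele_x", "other_allele_x", "effect_allele_y", "other_allele_y"):
        m[col] = m[col].str.upper()

    ea_x, oa_x = m["effect_allele_x"], m["other_allele_x"]
    ea_y, oa_y = m["effect_allele_y"], m["other_allele_y"]
    ea_yc, oa_yc = ea_y.map(_COMPLEMENT), oa_y.map(_COMPLEMENT)

    pal = _is_palindromic(ea_x, oa_x)
    same = (ea_y == ea_x) & (oa_y == oa_x)
    swapped = (ea_y == oa_x) & (oa_y == ea_x)
    flip_same = (ea_yc == ea_x) & (oa_yc == oa_x)
    flip_swapped = (ea_yc == oa_x) & (oa_yc == ea_x)

    keep = pd.Series(False, index=m.index)
    sign = pd.Series(1.0, index=m.index)

    keep |= ~pal & (same | flip_same)
    keep |= ~pal & (swapped | flip_swapped)
    sign[~pal & (swapped | flip_swapped)] = -1.0

    n_pal = 0
    if palindromic == "strict":
        n_pal = int(pal.sum())
        if n_pal:
            logger.info("DROP_PALINDROMIC %d SNP(s) in strict mode", n_pal)
    else:
        # palindromic alleles match either way; orient by decisive frequencies
        for col in ("eaf_x", "eaf_y"):
            if col not in m.columns:
                m[col] = np.nan
        have_eaf = pal & m["eaf_x"].notna() & m["eaf_y"].notna()
        decisive = (
            have_eaf
            & ((m["eaf_x"] - 0.5).abs() > eaf_threshold)
            & ((m["eaf_y"] - 0.5).abs() > eaf_threshold)
        )
        agree = (m["eaf_x"] - 0.5) * (m["eaf_y"] - 0.5) > 0
        keep |= pal & decisive & (same | swapped | flip_same | flip_swapped)
        sign[pal & decisive & ~agree] = -1.0
        n_pal = int((pal & ~(decisive & (same | swapped | flip_same | flip_swapped))).sum())
        if n_pal:
            logger.info("DROP_PALINDROMIC %d SNP(s) with indecisive frequency", n_pal)

    reconcilable = same | swapped | flip_same | flip_swapped
    mism = ~pal & ~reconcilable
    n_mismatch = int(mism.sum())
    for rsid in m.loc[mism, "snp"]:
        logger.info("DROP_ALLELE_MISMATCH %s irreconcilable allele pair", rsid)

    kept = m.loc[keep]
    if len(kept) == 0:
        raise ValueError("no SNPs retained after harmonization")
    return HarmonizedInstrument(
        rsid=kept["snp"].to_numpy(),
        x=kept["beta_x"].to_numpy(dtype=float),
        se_x=kept["se_x"].to_numpy(dtype=float),
        y=(kept["beta_y"] * sign.loc[kept.index]).to_numpy(dtype=float),
        se_y=kept["se_y"].to_numpy(dtype=float),
        n_input_exposure=n_input,
        n_dropped_missing=n_missing,
        n_dropped_info=n_info,
        n_dropped_palindromic=n_pal,
        n_dropped_mismatch=n_mismatch,
        exposure_unit=exposure_unit,
    )


def ivw_estimate(instrument: HarmonizedInstrument) -> MRResult:
    """Inverse-variance-weighted causal estimate (fixed-effect form)."""
    if instrument.n_snps == 0:
        raise ValueError("empty instrument")
    x, y, sy = instrument.x, instrument.y, instrument.se_y
    w = sy ** -2.0
    denom = float(np.sum(w * x ** 2))
    beta = float(np.sum(w * x * y)) / denom
    se = denom ** -0.5
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return MRResult(method="ivw", beta=beta, se=se, p=p, n_snps=instrument.n_snps)


def mr_egger(instrument: HarmonizedInstrument) -> MRResult:
    """MR-Egger regression: weighted fit of Y_g on X_g with a free intercept.

    Each SNP is first oriented so X_g >= 0 (flipping X and Y together),
    which makes the intercept interpretable as the average directional
    pleiotropic effect.  Weights are 1/sigma_Yg^2; standard errors use the
    estimated residual scale with n - 2 degrees of freedom.
    """
    n = instrument.n_snps
    if n < 3:
        raise ValueError("MR-Egger requires at least 3 SNPs")
    flip = np.where(instrument.x < 0, -1.0, 1.0)
    x, y = instrument.x * flip, instrument.y * flip
    w = instrument.se_y ** -2.0
    sw = np.sum(w)
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = float(np.sum(w * (x - xbar) ** 2))
    if sxx == 0:
        raise ValueError("no variation in instrument strength")
    slope = float(np.sum(w * (x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = y - intercept - slope * x
    s2 = float(np.sum(w * resid ** 2) / (n - 2))
    se_slope = math.sqrt(s2 / sxx)
    se_int = math.sqrt(s2 * (1.0 / sw + xbar ** 2 / sxx))

    def _p(value: float, se: float) -> float:
        if se == 0:  # exact fit: the estimate has no sampling noise
            return 0.0 if value != 0 else 1.0
        return float(2 * stats.t.sf(abs(value / se), n - 2))

    p_slope = _p(slope, se_slope)
    p_int = _p(intercept, se_int)
    return MRResult(
        method="egger", beta=slope, se=se_slope, p=p_slope, n_snps=n,
        intercept=intercept, se_intercept=se_int, p_intercept=p_int,
    )


def exclude_pleiotropic(
    instrument: HarmonizedInstrument, snp_ids: Iterable[str]
) -> HarmonizedInstrument:
    """Remove a pre-specified list of pleiotropic variants."""
    ids = set(snp_ids)
    unknown = ids - set(instrument.rsid)
    if unknown:
        logger.warning("exclusion list has %d id(s) not in the instrument", len(unknown))
    keep = ~np.isin(instrument.rsid, list(ids))
    if not keep.any():
        raise ValueError("exclusion removes every SNP in the instrument")
    return instrument.subset(keep)


def standardize_or(result: MRResult, exposure_unit_cm: float) -> MRResult:
    """Re-express a causal estimate per 10 cm of height and fill OR fields.

    ``exposure_unit_cm`` is the height increment, in cm, that one unit of
    the instrument's X_g corresponds to (e.g. the height SD when exposure
    betas are per SD; 1.0 when they are per cm).
    """
    if exposure_unit_cm <= 0:
        raise ValueError("exposure unit must be positive (cm)")
    scale = 10.0 / exposure_unit_cm
    beta, se = result.beta * scale, result.se * scale
    return replace(
        result, beta=beta, se=se, exposure_unit_cm=10.0,
        or_per_10cm=math.exp(beta),
        ci_low=math.exp(beta - Z975 * se),
        ci_high=math.exp(beta + Z975 * se),
    )


def mr_power(
    n_cases: float,
    n_controls: float,
    r2: float,
    or_alt: float,
    alpha: float = 0.05,
) -> float:
    """Analytic power of the IVW test against a case-control outcome.

    Non-centrality approximation for an instrument explaining a fraction
    ``r2`` of exposure variance: with ``N = n_cases + n_controls`` and case
    fraction ``phi``, the IVW z statistic is approximately normal with mean
    ``b = sqrt(N r2 phi (1 - phi)) |ln or_alt|`` (``or_alt`` per SD of the
    exposure).  Two-sided power at level ``alpha``:

        Phi(b - z_{1-alpha/2}) + Phi(-b - z_{1-alpha/2}),

    which reduces to ``alpha`` at ``or_alt = 1``.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 < r2 < 1):
        raise ValueError("r2 must be in (0, 1)")
    if or_alt <= 0:
        raise ValueError("or_alt must be positive")
    n = n_cases + n_controls
    phi = n_cases / n
    b = math.sqrt(n * r2 * phi * (1 - phi)) * abs(math.log(or_alt))
    z = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.cdf(b - z) + stats.norm.cdf(-b - z))
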