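"""Tabular dialects, SE/CI conversion, and result serialization.

Two table dialects are used throughout:

* GWAS summary statistics: tab-separated, header
  ``snp effect_allele other_allele eaf beta se pval info``
  (``eaf`` and ``info`` optional);
* study tables: comma-separated.  The ``summary`` dialect carries one row
  per study estimate (RR with 95% CI and the exposure increment it refers
  to); the ``categorical`` dialect carries one row per exposure category,
  grouped by ``study_id``.

Published RRs are converted to log scale with
``se = (ln ci_high - ln ci_low) / 3.92``; asymmetric intervals (log-scale
half-width ratio > 1.1) trigger a warning and use the average half-width.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Any, Literal, Sequence

import numpy as np
import pandas as pd

from .dose_response import CI_TO_SE_DIVISOR, CategoricalStudy, QuantileLevel
from .meta import StudyEstimate

logger = logging.getLogger("trendmr.io")

__version__ = "0.1.0"

SUMMARY_STAT_COLUMNS = ["snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "info"]
_REQUIRED_SUMMARY = ["snp", "effect_allele", "other_allele", "beta", "se", "pval"]
STRATA_COLUMNS = ["sex", "cancer_site", "colon_vs_rectum", "smoking_adjusted",
                  "height_measured", "ancestry"]


def rr_ci_to_log(rr: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """(log-RR, se) from a published RR and 95% CI."""
    if not (0 < ci_low < rr < ci_high):
        raise ValueError(f"CI ({ci_low}, {ci_high}) does not bracket rr={rr}")
    half_hi = math.log(ci_high / rr)
    half_lo = math.log(rr / ci_low)
    if max(half_hi / half_lo, half_lo / half_hi) > 1.1:
        logger.warning(
            "asymmetric CI (%.4g, %.4g) around rr=%.4g; using average half-width",
            ci_low, ci_high, rr,
        )
    return math.log(rr), (half_hi + half_lo) / CI_TO_SE_DIVISOR


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read a GWAS summary-statistic TSV into a typed table."""
    df = pd.read_csv(path, sep="\t", dtype={"snp": str})
    missing = [c for c in _REQUIRED_SUMMARY if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    if df["snp"].duplicated().any():
        dups = df.loc[df["snp"].duplicated(), "snp"].tolist()
        raise ValueError(f"{path}: duplicate snp id(s): {dups[:5]}")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    numeric = [c for c in ("eaf", "beta", "se", "pval", "info") if c in df.columns]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any() and col in ("beta", "se", "pval"):
            rows = (df.index[bad] + 2).tolist()  # 1-based, after header
            raise ValueError(f"{path}: unparseable {col} at file row(s) {rows[:5]}")
        df[col] = coerced
    return df


def write_summary_stats(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in SUMMARY_STAT_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols)


def _strata_from_row(row: pd.Series) -> dict[str, str]:
    return {
        k: str(row[k]) for k in STRATA_COLUMNS
        if k in row.index and pd.notna(row[k]) and str(row[k]) != ""
    }


def read_study_table(
    path: str | Path, dialect: Literal["summary", "categorical"] = "summary"
) -> list[StudyEstimate] | list[CategoricalStudy]:
    """Read a study-level CSV.

    ``summary`` rows carry ``study_id, rr, ci_low, ci_high, unit_cm`` plus
    optional strata columns; each row becomes a :class:`StudyEstimate` with
    the log effect rescaled to per 10 cm using its ``unit_cm``.
    ``categorical`` rows are grouped by ``study_id`` into
    :class:`CategoricalStudy` objects (a ``design`` column is required).
    """
    df = pd.read_csv(path)
    if dialect == "summary":
        estimates = []
        for _, row in df.iterrows():
            beta, se = rr_ci_to_log(row["rr"], row["ci_low"], row["ci_high"])
            unit = float(row.get("unit_cm", 10.0)) if pd.notna(row.get("unit_cm", 10.0)) else 10.0
            if unit <= 0:
                raise ValueError(f"{row['study_id']}: unit_cm must be positive")
            factor = 10.0 / unit
            estimates.append(StudyEstimate(
                study_id=str(row["study_id"]),
                beta=beta * factor,
                se=se * factor,
                strata=_strata_from_row(row),
            ))
        return estimates

    studies = []
    for study_id, grp in df.groupby("study_id", sort=False):
        grp = grp.sort_values("level_index")
        designs = grp["design"].unique()
        if len(designs) != 1:
            raise ValueError(f"{study_id}: conflicting design labels")
        levels = []
        for _, row in grp.iterrows():
            def opt(col: str) -> float | None:
                return float(row[col]) if col in row.index and pd.notna(row[col]) else None
            levels.append(QuantileLevel(
                rr=float(row["rr"]),
                n_cases=opt("n_cases"),
                n_total=opt("n_total"),
                person_time=opt("person_time"),
                lower_cm=opt("lower_cm"),
                upper_cm=opt("upper_cm"),
                score_cm=opt("score_cm"),
                ci_low=opt("ci_low"),
                ci_high=opt("ci_high"),
                is_reference=bool(row["is_reference"]),
            ))
        studies.append(CategoricalStudy(
            study_id=str(study_id), design=str(designs[0]), levels=levels,
            strata=_strata_from_row(grp.iloc[0]),
        ))
    return studies


def write_study_table(
    studies: Sequence[StudyEstimate] | Sequence[CategoricalStudy],
    path: str | Path,
    dialect: Literal["summary", "categorical"] = "summary",
) -> None:
    """Write study objects back to the CSV dialects (round-trip partner)."""
    rows = []
    if dialect == "summary":
        for e in studies:
            half = 1.959963984540054 * e.se
            rows.append({
                "study_id": e.study_id,
                "rr": math.exp(e.beta),
                "ci_low": math.exp(e.beta - half),
                "ci_high": math.exp(e.beta + half),
                "unit_cm": 10.0,
                **e.strata,
            })
    else:
        for s in studies:
            for i, lv in enumerate(s.levels):
                rows.append({
                    "study_id": s.study_id, "design": s.design, "level_index": i,
                    "lower_cm": lv.lower_cm, "upper_cm": lv.upper_cm,
                    "score_cm": lv.score_cm, "n_cases": lv.n_cases,
                    "n_total": lv.n_total, "person_time": lv.person_time,
                    "rr": lv.rr, "ci_low": lv.ci_low, "ci_high": lv.ci_high,
                    "is_reference": lv.is_reference, **s.strata,
                })
    pd.DataFrame(rows).to_csv(path, index=False)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def config_hash(config: Any) -> str:
    """Short deterministic hash of a config object or mapping."""
    payload = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_results(
    results: Any,
    path: str | Path,
    format: Literal["tsv", "json"] = "json",
    seed: int | None = None,
    config: Any = None,
) -> None:
    """Serialize stage results deterministically.

    TSV output requires a DataFrame and writes floats at full precision.
    JSON output wraps any dataclass / dict / DataFrame in an envelope with
    run metadata (seed, config hash, package version).
    """
    path = Path(path)
    if format == "tsv":
        if not isinstance(results, pd.DataFrame):
            raise TypeError("tsv format requires a DataFrame")
        results.to_csv(path, sep="\t", index=False, float_format="%.17g")
        return
    payload = {
        "run_meta": {
            "version": __version__,
            "seed": seed,
            "config_hash": config_hash(config) if config is not None else None,
        },
        "results": _jsonable(
            results.to_dict(orient="records") if isinstance(results, pd.DataFrame) else results
        ),
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")


def read_results(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    validate_results_payload(payload)
    return payload


def validate_results_payload(payload: dict) -> None:
    """Structural check of the JSON results envelope."""
    if not isinstance(payload, dict):
        raise ValueError("results payload must be an object")
    if set(payload) != {"run_meta", "results"}:
        raise ValueError("payload must have exactly the keys run_meta and results")
    meta = payload["run_meta"]
    if not isinstance(meta, dict) or not {"version", "seed", "config_hash"} <= set(meta):
        raise ValueError("run_meta must carry version, seed and config_hash")
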