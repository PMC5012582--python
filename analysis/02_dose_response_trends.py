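#!/usr/bin/env python
"""Convert each cohort's quantile table into a per-10-cm trend.

Applies category-mean scores, Greenland-Longnecker pseudo-counts, the GLS
trend through the reference category, and per-10-cm rescaling; writes
results/trend_estimates.tsv.
"""

import pathlib

import pandas as pd

from trendmr.dose_response import trend_from_study
from trendmr.io import read_study_table, write_results

ROOT = pathlib.Path(__file__).resolve().parents[1]
studies = read_study_table(ROOT / "results" / "data" / "cohort_quantiles.csv",
                           dialect="categorical")

rows = []
for study in studies:
    est = trend_from_study(study, scores="given", unit_cm=10.0)
    lo, hi = est.ci
    rows.append({"study_id": study.study_id, "rr_per_10cm": est.rr,
                 "ci_low": lo, "ci_high": hi, "log_rr": est.beta, "se": est.se,
                 "method": est.method})
    print(f"{study.study_id}: RR per 10 cm = {est.rr:.3f} ({lo:.3f}, {hi:.3f})")

table = pd.DataFrame(rows)
write_results(table, ROOT / "results" / "trend_estimates.tsv", format="tsv")
print(f"\nmean RR per 10 cm across cohorts: {table.rr_per_10cm.mean():.3f} "
      "(generating value 1.10); table -> results/trend_estimates.tsv")
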