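#!/usr/bin/env python
"""Generate the synthetic study inputs for the downstream analyses.

Emulates the three kinds of input the height-cancer analyses consume:

* a 423-SNP height instrument (16% of variance explained) with a paired
  case-control outcome GWAS at the colorectal-cancer sample sizes
  (5,100 cases / 4,831 controls) under a causal OR of 1.58 per 10 cm,
  with 77 instrument SNPs absent from the outcome panel;
* a 62-study collection of per-10-cm relative risks (true RR 1.10 per
  10 cm, between-study tau^2 = 0.01), with sex labels for subgrouping;
* four cohort quantile tables (200,000 subjects each) under the same
  log-linear trend, for the categorical-to-trend conversion.

Writes everything under results/data/.
"""

import math
import pathlib
import sys

from trendmr.io import write_study_table, write_summary_stats
from trendmr.simulate import (
    CohortSimConfig,
    MRSimConfig,
    StudySimConfig,
    simulate_cohort_study,
    simulate_mr_summary,
    simulate_study_collection,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)

# --- MR inputs -----------------------------------------------------------
mr_cfg = MRSimConfig(
    n_snps=423, r2_target=0.16, n_exposure=253_288,
    n_cases=5_100, n_controls=4_831,
    causal_beta=math.log(1.58) / 10,  # log-OR per cm
    seed=SEED,
)
exposure, outcome = simulate_mr_summary(mr_cfg)
outcome_panel = outcome.sample(n=423 - 77, random_state=SEED).sort_index()
write_summary_stats(exposure, OUT / "height_instrument.tsv")
write_summary_stats(outcome_panel, OUT / "colorectal_outcome.tsv")
(OUT / "pleiotropic_snps.txt").write_text(
    "\n".join(outcome_panel["snp"].iloc[:36]) + "\n")
print(f"MR inputs: {len(exposure)} exposure SNPs, {len(outcome_panel)} outcome SNPs "
      f"(77 missing from the outcome panel), 36-SNP pleiotropy exclusion list")

# --- study collection ----------------------------------------------------
study_cfg = StudySimConfig(
    n_studies=62, true_beta=math.log(1.10), tau2=0.01,
    se_range=(0.03, 0.25), seed=SEED + 1,
)
studies = simulate_study_collection(study_cfg)
for i, est in enumerate(studies):
    est.strata["sex"] = ("male", "female", "both")[i % 3]
write_study_table(studies, OUT / "prospective_studies.csv", dialect="summary")
print(f"study collection: {len(studies)} per-10-cm estimates, true RR 1.10, tau2 0.01")

# --- cohort quantile tables ----------------------------------------------
cohorts = []
for j in range(4):
    cohorts.append(simulate_cohort_study(CohortSimConfig(
        n_subjects=200_000, beta_per_cm=math.log(1.10) / 10, seed=SEED + 10 + j)))
write_study_table(cohorts, OUT / "cohort_quantiles.csv", dialect="categorical")
print(f"cohorts: {len(cohorts)} quintile tables from 200,000-subject cohorts, "
      "true RR 1.10 per 10 cm")
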