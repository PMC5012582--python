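"""Harmonization, IVW, MR-Egger, exclusions, standardization, power."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from trendmr.mr import (
    exclude_pleiotropic,
    filter_info,
    harmonize,
    ivw_estimate,
    mr_egger,
    mr_power,
    standardize_or,
)
from trendmr.simulate import MRSimConfig, replicate, simulate_mr_summary

from conftest import instrument_from_frames

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@pytest.fixture
def paired_tables():
    return simulate_mr_summary(MRSimConfig(n_snps=60, causal_beta=0.02, seed=13))


class TestHarmonize:
    def test_aligned_tables_pass_through(self, paired_tables):
        exposure, outcome = paired_tables
        inst = harmonize(exposure, outcome)
        assert inst.n_snps == 60
        np.testing.assert_allclose(inst.y, outcome["beta"].to_numpy())

    def test_swapped_alleles_flip_outcome_sign(self, paired_tables):
        exposure, outcome = paired_tables
        ref = harmonize(exposure, outcome)
        flipped = outcome.copy()
        i = 7
        flipped.loc[i, ["effect_allele", "other_allele"]] = (
            outcome.loc[i, "other_allele"], outcome.loc[i, "effect_allele"])
        flipped.loc[i, "beta"] = -outcome.loc[i, "beta"]
        flipped.loc[i, "eaf"] = 1 - outcome.loc[i, "eaf"]
        inst = harmonize(exposure, flipped)
        np.testing.assert_allclose(inst.y, ref.y)

    def test_strand_flip_is_reconciled(self, paired_tables):
        exposure, outcome = paired_tables
        ref = harmonize(exposure, outcome)
        flipped = outcome.copy()
        for i in (3, 4):
            flipped.loc[i, "effect_allele"] = _COMP[outcome.loc[i, "effect_allele"]]
            flipped.loc[i, "other_allele"] = _COMP[outcome.loc[i, "other_allele"]]
        inst = harmonize(exposure, flipped)
        np.testing.assert_allclose(inst.y, ref.y)
        assert inst.n_dropped_mismatch == 0

    def test_missing_outcome_snps_dropped_and_counted(self, paired_tables):
        exposure, outcome = paired_tables
        inst = harmonize(exposure, outcome.iloc[10:])
        assert inst.n_snps == 50
        assert inst.n_dropped_missing == 10
        assert inst.n_input_exposure == 60

    def test_palindromic_policies(self):
        def table(beta, eaf):
            return pd.DataFrame({
                "snp": ["rs1"], "effect_allele": ["A"], "other_allele": ["T"],
                "eaf": [eaf], "beta": [beta], "se": [0.1], "pval": [0.5], "info": [1.0],
            })

        exposure = table(0.2, 0.3)
        with pytest.raises(ValueError, match="no SNPs"):
            harmonize(exposure, table(0.1, 0.3), palindromic="strict")
        # decisive, agreeing frequencies: kept as-is
        inst = harmonize(exposure, table(0.1, 0.3), palindromic="freq")
        assert inst.n_snps == 1 and inst.y[0] == pytest.approx(0.1)
        # decisive, opposite frequencies: orientation flipped
        inst = harmonize(exposure, table(0.1, 0.7), palindromic="freq")
        assert inst.y[0] == pytest.approx(-0.1)
        # indecisive frequency: dropped
        with pytest.raises(ValueError, match="no SNPs"):
            harmonize(exposure, table(0.1, 0.52), palindromic="freq")

    def test_info_filter_counted(self, paired_tables):
        exposure, outcome = paired_tables
        low = outcome.copy()
        low.loc[0:4, "info"] = 0.1
        inst = harmonize(exposure, low, info_threshold=0.3)
        assert inst.n_snps == 55
        assert inst.n_dropped_info == 5

    def test_idempotent(self, paired_tables):
        exposure, outcome = paired_tables
        first = harmonize(exposure, outcome)
        aligned = outcome.copy()
        aligned["beta"] = first.y
        aligned["effect_allele"] = exposure["effect_allele"]
        aligned["other_allele"] = exposure["other_allele"]
        second = harmonize(exposure, aligned)
        np.testing.assert_array_equal(first.y, second.y)
        np.testing.assert_array_equal(first.x, second.x)


class TestFilterInfo:
    def test_stated_cutoffs(self):
        df = pd.DataFrame({"snp": ["a", "b", "c"], "info": [0.2, 0.3, 0.9]})
        assert len(filter_info(df, 0.3)) == 2       # boundary kept: rule is info < 0.3
        assert len(filter_info(df, 0.7)) == 1
        assert len(filter_info(df, 0.0)) == 3

    def test_missing_column_passes_with_warning(self, caplog):
        df = pd.DataFrame({"snp": ["a"], "beta": [0.1]})
        out = filter_info(df, 0.3)
        assert len(out) == 1
        assert out.attrs["n_dropped_info"] == 0


class TestIVW:
    def test_single_snp_is_wald_ratio(self):
        inst = instrument_from_frames(
            pd.DataFrame({"snp": ["rs1"], "beta": [0.10], "se": [0.01]}),
            pd.DataFrame({"snp": ["rs1"], "beta": [0.02], "se": [0.01]}),
        )
        res = ivw_estimate(inst)
        assert res.beta == pytest.approx(0.2, abs=1e-15)
        assert res.se == pytest.approx(0.1, abs=1e-15)

    def test_zero_outcome_effects_give_zero(self, paired_tables):
        exposure, outcome = paired_tables
        outcome = outcome.copy()
        outcome["beta"] = 0.0
        assert ivw_estimate(instrument_from_frames(exposure, outcome)).beta == 0.0

    def test_matches_wls_through_origin_oracle(self, paired_tables):
        import statsmodels.api as sm

        inst = instrument_from_frames(*paired_tables)
        res = ivw_estimate(inst)
        fit = sm.WLS(inst.y, inst.x, weights=inst.se_y**-2).fit()
        assert res.beta == pytest.approx(fit.params[0], abs=1e-12)

    def test_orientation_invariance(self, paired_tables):
        inst = instrument_from_frames(*paired_tables)
        flipped = dataclasses.replace(inst, x=inst.x.copy(), y=inst.y.copy())
        flipped.x[::2] *= -1
        flipped.y[::2] *= -1
        assert ivw_estimate(flipped).beta == pytest.approx(ivw_estimate(inst).beta, rel=1e-12)

    def test_removing_snp_at_pooled_ratio_is_neutral(self):
        x = np.array([0.1, 0.2, 0.3])
        y = np.array([0.01, 0.05, 0.02])
        se = np.array([0.02, 0.03, 0.01])
        inst = instrument_from_frames(
            pd.DataFrame({"snp": ["a", "b", "c"], "beta": x, "se": se}),
            pd.DataFrame({"snp": ["a", "b", "c"], "beta": y, "se": se}),
        )
        b = ivw_estimate(inst).beta
        extended = instrument_from_frames(
            pd.DataFrame({"snp": list("abcd"), "beta": np.append(x, 0.15),
                          "se": np.append(se, 0.02)}),
            pd.DataFrame({"snp": list("abcd"), "beta": np.append(y, b * 0.15),
                          "se": np.append(se, 0.02)}),
        )
        assert ivw_estimate(extended).beta == pytest.approx(b, rel=1e-12)


class TestEgger:
    def test_exact_linear_data(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        inst = instrument_from_frames(
            pd.DataFrame({"snp": list("abcd"), "beta": x, "se": 0.01 * np.ones(4)}),
            pd.DataFrame({"snp": list("abcd"), "beta": 0.5 * x, "se": 0.01 * np.ones(4)}),
        )
        res = mr_egger(inst)
        assert res.beta == pytest.approx(0.5, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_weighted_ols_oracle(self, paired_tables):
        import statsmodels.api as sm

        inst = instrument_from_frames(*paired_tables)
        res = mr_egger(inst)
        flip = np.where(inst.x < 0, -1.0, 1.0)
        x, y = inst.x * flip, inst.y * flip
        fit = sm.WLS(y, sm.add_constant(x), weights=inst.se_y**-2).fit()
        assert res.intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert res.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert res.se == pytest.approx(fit.bse[1], abs=1e-10)
        assert res.p_intercept == pytest.approx(fit.pvalues[0], abs=1e-10)

    def test_agrees_with_ivw_when_intercept_constrained(self, paired_tables):
        """Constraining the Egger intercept to zero recovers the IVW slope
        on orientation-fixed data."""
        inst = instrument_from_frames(*paired_tables)
        ivw = ivw_estimate(inst)
        w = inst.se_y**-2
        slope_no_intercept = float(np.sum(w * inst.x * inst.y) / np.sum(w * inst.x**2))
        assert slope_no_intercept == pytest.approx(ivw.beta, abs=1e-10)

    def test_requires_three_snps(self):
        inst = instrument_from_frames(
            pd.DataFrame({"snp": ["a", "b"], "beta": [0.1, 0.2], "se": [0.01, 0.01]}),
            pd.DataFrame({"snp": ["a", "b"], "beta": [0.1, 0.2], "se": [0.01, 0.01]}),
        )
        with pytest.raises(ValueError):
            mr_egger(inst)


class TestExcludeAndStandardize:
    def test_exclusion_bookkeeping(self, paired_tables):
        inst = instrument_from_frames(*paired_tables)
        smaller = exclude_pleiotropic(inst, list(inst.rsid[:10]))
        assert smaller.n_snps == 50
        assert exclude_pleiotropic(inst, []).n_snps == inst.n_snps

    def test_unknown_ids_warn_and_pass(self, paired_tables, caplog):
        inst = instrument_from_frames(*paired_tables)
        out = exclude_pleiotropic(inst, ["rs_not_there"])
        assert out.n_snps == inst.n_snps

    def test_emptying_instrument_errors(self, paired_tables):
        inst = instrument_from_frames(*paired_tables)
        with pytest.raises(ValueError):
            exclude_pleiotropic(inst, list(inst.rsid))

    def test_standardize_examples(self, paired_tables):
        res = ivw_estimate(instrument_from_frames(*paired_tables))
        per_cm = dataclasses.replace(res, beta=0.05, se=0.01)
        out = standardize_or(per_cm, 1.0)
        assert out.or_per_10cm == pytest.approx(math.exp(0.5), rel=1e-12)
        ident = standardize_or(dataclasses.replace(res, beta=0.05, se=0.01), 10.0)
        assert ident.beta == pytest.approx(0.05, abs=1e-15)
        per_sd = standardize_or(dataclasses.replace(res, beta=0.07, se=0.01), 7.0)
        assert per_sd.or_per_10cm == pytest.approx(math.exp(0.10), rel=1e-12)
        assert per_sd.ci_low == pytest.approx(math.exp(0.10 - 1.96 * 0.10 / 7), rel=1e-4)

    def test_bad_unit_errors(self, paired_tables):
        res = ivw_estimate(instrument_from_frames(*paired_tables))
        with pytest.raises(ValueError):
            standardize_or(res, 0.0)


class TestPower:
    def test_null_effect_gives_alpha(self):
        assert mr_power(5000, 5000, 0.1, 1.0) == pytest.approx(0.05, abs=1e-12)
        assert mr_power(5000, 5000, 0.1, 1.0, alpha=0.01) == pytest.approx(0.01, abs=1e-12)

    def test_monotone_in_effect_and_n(self):
        assert mr_power(5000, 5000, 0.1, 1.2) > mr_power(5000, 5000, 0.1, 1.1)
        assert mr_power(20000, 20000, 0.1, 1.1) > mr_power(5000, 5000, 0.1, 1.1)

    def test_matches_empirical_rejection_rate(self):
        """The analytic approximation tracks the IVW test's simulated
        rejection rate to within 2 percentage points."""
        sd = 7.0
        causal_per_cm = math.log(1.08) / sd  # OR 1.08 per SD of height
        cfg = MRSimConfig(
            n_snps=150, r2_target=0.10, n_exposure=250_000,
            n_cases=5000, n_controls=5000, causal_beta=causal_per_cm,
            exposure_sd_cm=sd, seed=40_000,
        )
        predicted = mr_power(5000, 5000, 0.10, 1.08)
        rejections = 0
        n_rep = 2000
        for k in range(n_rep):
            inst = instrument_from_frames(*simulate_mr_summary(replicate(cfg, k)))
            rejections += ivw_estimate(inst).p < 0.05
        assert rejections / n_rep == pytest.approx(predicted, abs=0.02)
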