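import warnings

import numpy as np
import pandas as pd
import pytest

from hemovalid import (
    AgreementAnalysis,
    agreement_table,
    bland_altman,
    bp_error_bins,
    icc_sem,
    normality_tests,
    pearson_regression,
    percentage_error,
)
from hemovalid.agreement import DegenerateInputError

from _oracles import icc_a1_oracle, ols_oracle, pearson_oracle


class TestPearsonRegression:
    def test_identity_pairs(self):
        out = pearson_regression([1, 2, 3], [1, 2, 3])
        assert out["r"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(1.0)
        assert out["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_anticorrelation(self):
        assert pearson_regression([1, 2, 3], [3, 2, 1])["r"] == pytest.approx(-1.0)

    def test_hand_oracle_value(self):
        out = pearson_regression([1, 2, 3, 4], [2, 1, 4, 3])
        assert out["r"] == pytest.approx(0.6)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_regression([1.0, 1.0, 1.0], [2.0, 3.0, 4.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_regression([1, 2], [1, 2])


class TestICC:
    def test_identical_pairs_perfect_agreement(self):
        out = icc_sem([3, 7, 11, 5], [3, 7, 11, 5])
        assert out["icc"] == pytest.approx(1.0)
        assert out["sem_measurement"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_penalized(self):
        # absolute agreement: a systematic +1 offset keeps ICC strictly < 1;
        # frozen value from the explicit two-way ANOVA on this 3x2 table
        out = icc_sem([1, 2, 3], [2, 3, 4])
        assert out["icc"] == pytest.approx(2.0 / 3.0, abs=1e-12)
        assert out["sem_measurement"] == pytest.approx(0.6055300708, abs=1e-9)
        assert out["icc"] == pytest.approx(icc_a1_oracle([1, 2, 3], [2, 3, 4]),
                                           abs=1e-12)

    def test_degenerate_table_flagged(self):
        out = icc_sem([5, 5, 5], [5, 5, 5])
        assert out["degenerate"]

    def test_negative_estimate_clamped(self):
        out = icc_sem([1, 2, 3, 4], [4, 3, 2, 1])
        assert out["icc"] == 0.0
        assert out["clamped"]

    def test_matches_pingouin_icc_a1(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        for _ in range(5):
            n = rng.integers(5, 15)
            r = rng.normal(50, 10, n)
            d = r + rng.normal(1, 4, n)
            df = pd.DataFrame({
                "targets": np.repeat(np.arange(n), 2),
                "raters": ["ref", "dev"] * n,
                "score": np.column_stack([r, d]).ravel(),
            })
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tab = pingouin.intraclass_corr(df, targets="targets",
                                               raters="raters", ratings="score")
            expect = float(tab.loc[tab.Type == "ICC(A,1)", "ICC"].iloc[0])
            assert icc_sem(r, d)["icc"] == pytest.approx(expect, abs=1e-10)


class TestOracleEquivalence:
    def test_pearson_ols_icc_match_brute_force(self):
        """r, OLS slope/intercept and ICC(A,1) equal naive-formula oracles to
        1e-10 on random small tables."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(4, 21))
            ref = rng.normal(60, 15, n)
            dev = 0.3 * rng.normal() + ref * (1 + 0.1 * rng.normal()) \
                + rng.normal(0, 5, n)
            dev = np.abs(dev) + 1.0
            out = pearson_regression(ref, dev)
            slope, intercept = ols_oracle(ref, dev)
            assert out["r"] == pytest.approx(pearson_oracle(ref, dev), abs=1e-10)
            assert out["slope"] == pytest.approx(slope, abs=1e-10)
            assert out["intercept"] == pytest.approx(intercept, abs=1e-10)
            icc = icc_sem(ref, dev)["icc"]
            oracle = icc_a1_oracle(ref, dev)
            if oracle >= 0:
                assert icc == pytest.approx(oracle, abs=1e-10)


class TestBlandAltman:
    def test_identical_pairs(self):
        out = bland_altman([4, 5, 6], [4, 5, 6])
        assert out["bias"] == 0.0
        assert out["loa_lower"] == 0.0 and out["loa_upper"] == 0.0

    def test_hand_worked_differences(self):
        # differences {1, 2, 3}: bias 2, sd 1, LOA (0.04, 3.96)
        out = bland_altman([10, 10, 10], [11, 12, 13])
        assert out["bias"] == pytest.approx(2.0)
        assert out["sd_diff"] == pytest.approx(1.0)
        assert out["loa_lower"] == pytest.approx(0.04)
        assert out["loa_upper"] == pytest.approx(3.96)

    def test_sign_flip_mirrors_limits(self):
        a = bland_altman([10, 10, 10], [11, 12, 13])
        b = bland_altman([11, 12, 13], [10, 10, 10])
        assert b["bias"] == pytest.approx(-a["bias"])
        assert b["loa_lower"] == pytest.approx(-a["loa_upper"])
        assert b["loa_upper"] == pytest.approx(-a["loa_lower"])

    def test_parameter_recovery_known_noise(self):
        rng = np.random.default_rng(7)
        n = 4000
        ref = rng.normal(70, 12, n)
        dev = ref + 4.0 + rng.normal(0, 6.0, n)
        out = bland_altman(ref, dev)
        se = 6.0 / np.sqrt(n)
        assert out["bias"] == pytest.approx(4.0, abs=3 * se)
        half = (out["loa_upper"] - out["loa_lower"]) / 2
        assert half == pytest.approx(1.96 * 6.0, rel=0.05)


class TestPercentageError:
    def test_identical_pairs_zero(self):
        assert percentage_error([4, 4, 4], [4, 4, 4]) == 0.0

    def test_hand_worked_value(self):
        # sd of {.5,-.5,.5,-.5} = 0.5774; 100*1.96*sd/4 = 28.3%
        pe = percentage_error([4.0] * 4, [4.5, 3.5, 4.5, 3.5])
        assert pe == pytest.approx(28.29, abs=0.01)

    def test_scale_invariance(self):
        ref = np.array([3.0, 4.0, 5.0, 4.5])
        dev = np.array([3.5, 3.8, 5.4, 4.2])
        assert percentage_error(ref, dev) == pytest.approx(
            percentage_error(10 * ref, 10 * dev))


class TestBpErrorBins:
    def test_identical_pairs_all_within(self):
        out = bp_error_bins([80, 90], [80, 90])
        assert out == {"within_5": 100.0, "within_10": 100.0, "within_15": 100.0}

    def test_counting(self):
        ref = [100.0] * 4
        dev = [100.0, 106.0, 112.0, 120.0]
        out = bp_error_bins(ref, dev)
        assert out["within_5"] == 25.0
        assert out["within_10"] == 50.0
        assert out["within_15"] == 75.0

    def test_inclusive_boundary(self):
        out = bp_error_bins([100.0, 100.0], [115.0, 85.0])
        assert out["within_15"] == 100.0

    def test_nesting_invariant_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ref = rng.uniform(40, 120, 30)
            dev = ref + rng.normal(0, 12, 30)
            out = bp_error_bins(ref, dev)
            assert out["within_5"] <= out["within_10"] <= out["within_15"]


class TestNormality:
    def test_constant_input_degenerate(self):
        out = normality_tests([2.0, 2.0, 2.0, 2.0])
        assert out["degenerate"]
        assert np.isnan(out["ks_p"]) and np.isnan(out["sw_p"])

    def test_gaussian_sample_usually_passes(self):
        rng = np.random.default_rng(11)
        ok = 0
        reps = 40
        for _ in range(reps):
            out = normality_tests(rng.normal(0, 1, 500))
            if out["ks_p"] >= 0.01 and out["sw_p"] >= 0.01:
                ok += 1
        assert ok >= 0.9 * reps

    def test_bimodal_sample_rejected(self):
        rng = np.random.default_rng(12)
        rejected = 0
        reps = 20
        for _ in range(reps):
            v = np.concatenate([rng.normal(-4, 0.5, 100), rng.normal(4, 0.5, 100)])
            if normality_tests(v)["sw_p"] < 0.05:
                rejected += 1
        assert rejected >= 0.9 * reps


class TestAgreementTable:
    def test_perfect_fixture_all_strata_perfect(self, perfect_fixture):
        for res in agreement_table(perfect_fixture):
            assert res.pearson_r == pytest.approx(1.0)
            assert res.icc == pytest.approx(1.0)
            assert res.bias == 0.0
            assert res.loa_lower == 0.0 and res.loa_upper == 0.0

    def test_biased_fixture_recovers_offset(self, biased_fixture):
        results = AgreementAnalysis(biased_fixture).fit()
        sbp = results.get("SBP", "all")
        assert sbp.bias == pytest.approx(4.0)
        assert sbp.loa_upper - sbp.loa_lower == pytest.approx(0.0, abs=1e-9)
        assert sbp.within_5 == 100.0
        hr = results.get("HR", "all")
        assert hr.bias == 0.0

    def test_strata_counts_partition(self, default_cohort, recwarn):
        results = AgreementAnalysis(default_cohort).fit()
        for var in ("SBP", "DBP", "HR", "CO"):
            per_phase = [r.n for r in results if r.variable == var
                         and r.stratum != "all"]
            pooled = results.get(var, "all").n
            assert sum(per_phase) == pooled

    def test_loa_half_width_recovers_generator_noise(self):
        """With pure additive device noise of known SD, the fitted LOA
        half-width approaches 1.96 sigma."""
        from conftest import degenerate_config
        from hemovalid import simulate_experiment
        from hemovalid.synthetic_cohort import DeviceErrorModel
        sigma = 5.0
        cfg = degenerate_config(seed=8, n_animals=40)
        cfg.device = DeviceErrorModel(
            calibration_offset_sd={v: 0.0 for v in ("SBP", "DBP", "HR", "CO")},
            proportional_bias=0.0,
            noise_sd={"SBP": sigma, "DBP": sigma, "HR": sigma, "CO": 0.0},
            ar1_rho=0.0,
        )
        ds = simulate_experiment(cfg)
        res = AgreementAnalysis(ds).fit().get("SBP", "all")
        half = (res.loa_upper - res.loa_lower) / 2
        assert half == pytest.approx(1.96 * sigma, rel=0.05)
        assert abs(res.bias) < 3 * sigma / np.sqrt(res.n)

    def test_icc_decreases_and_loa_widens_with_noise(self):
        rng = np.random.default_rng(21)
        ref = rng.normal(70, 15, 5000)
        iccs, widths = [], []
        for sd in (2.0, 6.0, 12.0):
            dev = ref + rng.normal(0, sd, len(ref))
            iccs.append(icc_sem(ref, dev)["icc"])
            ba = bland_altman(ref, dev)
            widths.append(ba["loa_upper"] - ba["loa_lower"])
        assert iccs[0] > iccs[1] > iccs[2]
        assert widths[0] < widths[1] < widths[2]

    def test_small_stratum_skipped_with_warning(self):
        from hemovalid import Dataset
        df = pd.DataFrame({
            "animal_id": "A1", "phase": "pre_bleeding",
            "time_min": [0.0, 5.0], "variable": "SBP",
            "reference_value": [80.0, 82.0], "device_value": [81.0, 83.0],
        })
        with pytest.warns(UserWarning, match="skipped"):
            results = AgreementAnalysis(Dataset(df)).fit()
        assert len(results) == 0
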