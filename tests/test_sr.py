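"""Normative line fitting, outlier gating and SR residualization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from srres import SimConfig, generate_cohort
from srres.sr import (average_sr, compute_sr, fit_normative_mixed,
                      fit_normative_ols, mahalanobis_outliers)
from srres.sr import test_polynomial_term as polynomial_term_check
from srres.synth import null_config


class TestMahalanobis:
    def test_point_at_centroid_retained(self):
        rng = np.random.default_rng(0)
        e = np.r_[rng.normal(10, 2, 50), 10.0]
        p = np.r_[rng.normal(5, 1, 50), 5.0]
        e[-1], p[-1] = e[:-1].mean(), p[:-1].mean()
        keep, d2, _ = mahalanobis_outliers(e, p)
        assert keep[-1]
        assert d2[-1] < 0.5

    def test_offset_pair_against_chi_square_oracle(self):
        # near-identity sample covariance with one pair offset (4, 4):
        # D^2 ~ 32 exceeds the chi2(2) 0.999 quantile 13.8155
        rng = np.random.default_rng(1)
        e = rng.normal(0, 1, 4000)
        p = rng.normal(0, 1, 4000)
        e[-1], p[-1] = 4.0, 4.0
        keep, d2, thr = mahalanobis_outliers(e, p)
        assert thr == pytest.approx(stats.chi2.ppf(0.999, 2), abs=1e-9)
        assert thr == pytest.approx(13.8155, abs=1e-3)
        assert d2[-1] == pytest.approx(32.0, rel=0.1)
        assert not keep[-1]

    def test_singular_covariance_raises(self):
        e = np.arange(10.0)
        with pytest.raises(np.linalg.LinAlgError, match="jitter"):
            mahalanobis_outliers(e, 2 * e)

    def test_requires_three_pairs(self):
        with pytest.raises(ValueError):
            mahalanobis_outliers([1, 2], [3, 4])


class TestNormativeOLS:
    def test_collinear_points_exact(self):
        e = np.array([0.0, 10, 20, 30])
        line = fit_normative_ols(e, 2 + 0.1 * e)
        assert line.intercept == pytest.approx(2.0, abs=1e-10)
        assert line.slope == pytest.approx(0.1, abs=1e-12)

    def test_five_point_toy_matches_normal_equations(self):
        e = np.array([1.0, 2, 4, 7, 11])
        p = np.array([3.0, 1, 6, 5, 9])
        line = fit_normative_ols(e, p)
        slope = ((e - e.mean()) @ (p - p.mean())) / ((e - e.mean()) @ (e - e.mean()))
        intercept = p.mean() - slope * e.mean()
        assert line.slope == pytest.approx(slope, abs=1e-12)
        assert line.intercept == pytest.approx(intercept, abs=1e-12)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(2)
        e = rng.normal(40, 10, 100)
        p = 5 + 0.1 * e + rng.normal(0, 2, 100)
        l0 = fit_normative_ols(e, p)
        l1 = fit_normative_ols(e, p + 3.0)
        assert l1.intercept - l0.intercept == pytest.approx(3.0, abs=1e-9)
        assert l1.slope == pytest.approx(l0.slope, abs=1e-12)

    def test_zero_exposure_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_normative_ols([5, 5, 5, 5], [1, 2, 3, 4])


class TestNormativeMixed:
    def test_degenerate_noise_free_recovers_generating_line(self):
        cfg = null_config(60, seed=4, sd_random_intercept=0.0, residual_sd=1e-3)
        _, weekly, _ = generate_cohort(cfg)
        line = fit_normative_mixed(weekly)
        assert line.intercept == pytest.approx(cfg.ep_intercept, abs=0.02)
        assert line.slope == pytest.approx(cfg.ep_slope, abs=0.001)

    def test_single_observation_per_participant_reduces_to_ols(self):
        cfg = null_config(150, seed=6)
        _, weekly, _ = generate_cohort(cfg)
        w0 = weekly[weekly.t == 0]
        mixed = fit_normative_mixed(w0)
        ols = fit_normative_ols(w0["E"], w0["P"])
        assert mixed.intercept == pytest.approx(ols.intercept, abs=1e-3)
        assert mixed.slope == pytest.approx(ols.slope, abs=1e-5)

    def test_zero_random_variance_matches_ols_on_pooled_rows(self):
        cfg = null_config(120, seed=14, sd_random_intercept=0.0)
        _, weekly, _ = generate_cohort(cfg)
        mixed = fit_normative_mixed(weekly)
        ols = fit_normative_ols(weekly["E"], weekly["P"])
        assert mixed.intercept == pytest.approx(ols.intercept, abs=5e-2)
        assert mixed.slope == pytest.approx(ols.slope, abs=1e-3)

    def test_fixed_effects_recover_generating_values(self):
        cfg = null_config(200, seed=31, sd_random_slope=0.03)
        _, weekly, _ = generate_cohort(cfg)
        line = fit_normative_mixed(weekly)
        assert line.method == "mixed_fixed_effects"
        assert abs(line.intercept - cfg.ep_intercept) < 1.96 * line.intercept_se * 1.5
        assert abs(line.slope - cfg.ep_slope) < 1.96 * line.slope_se * 1.5


class TestPolynomialCheck:
    def test_exactly_linear_data_gives_zero_statistic(self):
        e = np.arange(1.0, 41)
        df = pd.DataFrame({"participant_id": np.arange(40), "E": e, "P": 2 + 0.1 * e})
        out = polynomial_term_check(df, method="cross")
        assert out["statistic"] == pytest.approx(0.0, abs=1e-6)
        assert out["p"] == pytest.approx(1.0, abs=1e-6)

    def test_strong_quadratic_detected(self):
        rng = np.random.default_rng(8)
        e = rng.normal(40, 12, 500)
        p = 5 + 0.1 * e + 0.01 * e**2 + rng.normal(0, 2, 500)
        df = pd.DataFrame({"participant_id": np.arange(500), "E": e, "P": p})
        assert polynomial_term_check(df, method="cross")["p"] < 1e-3

    def test_longitudinal_quadratic_detected_and_null_calibrated(self):
        cfg = null_config(150, seed=9)
        _, weekly, _ = generate_cohort(cfg)
        out = polynomial_term_check(weekly, method="long")
        assert out["test"] == "LRT"
        assert out["p"] > 0.001  # linear generator: no strong curvature signal
        quad = weekly.assign(P=weekly.P + 0.005 * weekly.E**2)
        assert polynomial_term_check(quad, method="long")["p"] < 1e-3


class TestSRScores:
    def test_observation_on_the_line_scores_zero(self):
        line = fit_normative_ols(np.array([0.0, 10, 20]), np.array([2.0, 3, 4]))
        df = pd.DataFrame({"E": [10.0], "P": [3.0]})
        assert compute_sr(line, df)["sr"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_arithmetic_example(self):
        from srres.sr import NormativeLine
        line = NormativeLine(intercept=2.0, slope=0.1, method="ols", n_obs=10)
        df = pd.DataFrame({"E": [10.0], "P": [5.0]})
        assert compute_sr(line, df)["sr"].iloc[0] == pytest.approx(2.0)

    def test_ols_residual_orthogonality(self, default_cohort):
        _, _, weekly, _ = default_cohort
        w0 = weekly[weekly.t == 0]
        line = fit_normative_ols(w0["E"], w0["P"])
        sr = compute_sr(line, w0)["sr"].to_numpy()
        assert abs(sr.mean()) < 1e-10
        assert abs(np.corrcoef(sr, w0["E"])[0, 1]) < 1e-10

    def test_translation_equivariance_of_sr(self, default_cohort):
        _, _, weekly, _ = default_cohort
        w0 = weekly[weekly.t == 0].copy()
        line0 = fit_normative_ols(w0["E"], w0["P"])
        sr0 = compute_sr(line0, w0)["sr"]
        w1 = w0.assign(P=w0["P"] + 7.0)
        line1 = fit_normative_ols(w1["E"], w1["P"])
        sr1 = compute_sr(line1, w1)["sr"]
        np.testing.assert_allclose(sr0, sr1, atol=1e-9)

    def test_sr_ranking_invariant_to_affine_exposure_rescaling(self, default_cohort):
        _, _, weekly, _ = default_cohort
        w0 = weekly[weekly.t == 0].copy()
        sr0 = compute_sr(fit_normative_ols(w0["E"], w0["P"]), w0)["sr"]
        w1 = w0.assign(E=2.5 * w0["E"] + 3.0)
        sr1 = compute_sr(fit_normative_ols(w1["E"], w1["P"]), w1)["sr"]
        assert stats.spearmanr(sr0, sr1).statistic == pytest.approx(1.0)

    def test_outlier_rows_get_missing_sr_by_default(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"E": rng.normal(40, 10, 200), "P": rng.normal(13, 4, 200)})
        df.loc[0, ["E", "P"]] = [150.0, 36.0]
        keep, _, _ = mahalanobis_outliers(df["E"], df["P"])
        line = fit_normative_ols(df["E"][keep], df["P"][keep])
        scored = compute_sr(line, df, retain_mask=keep)
        assert scored["sr"].isna().iloc[0]
        assert scored["sr"].notna().iloc[1:].all()
        rescored = compute_sr(line, df, retain_mask=keep, include_excluded=True)
        assert rescored["sr"].notna().all()

    def test_missing_inputs_propagate(self):
        from srres.sr import NormativeLine
        line = NormativeLine(intercept=0.0, slope=1.0, method="ols", n_obs=5)
        df = pd.DataFrame({"E": [1.0, np.nan], "P": [np.nan, 2.0]})
        assert compute_sr(line, df)["sr"].isna().all()


class TestAverageSR:
    @pytest.mark.parametrize("vals,expected", [
        ([1.0, -1.0, 0.0, 0.0], 0.0),
        ([0.7], 0.7),
        ([2.5] * 5, 2.5),
    ])
    def test_follow_up_mean(self, vals, expected):
        df = pd.DataFrame({"participant_id": 1, "t": np.arange(1, len(vals) + 1),
                           "sr": vals})
        assert average_sr(df).loc[1] == pytest.approx(expected)

    def test_baseline_excluded(self):
        df = pd.DataFrame({"participant_id": [1, 1, 1], "t": [0, 1, 2],
                           "sr": [100.0, 1.0, 3.0]})
        assert average_sr(df).loc[1] == pytest.approx(2.0)
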