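"""Standardized association models and mediation machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srres import generate_cohort
from srres.regression import (baron_kenny, distribution_of_product_ci,
                              fit_rf_model, run_h1, standardize_frame)
from srres.sr import compute_sr, fit_normative_ols
from srres.synth import calibrate_effect, null_config


class TestStandardize:
    def test_unit_spaced_triplet(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        np.testing.assert_allclose(standardize_frame(df, ["x"])["x"],
                                   [-1.0, 0.0, 1.0])

    def test_idempotent_on_z_scores(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(0, 1, 50)})
        z1 = standardize_frame(df, ["x"])
        z2 = standardize_frame(z1, ["x"])
        np.testing.assert_allclose(z1["x"], z2["x"], atol=1e-12)

    @given(st.floats(0.1, 50), st.floats(-100, 100))
    @settings(max_examples=40, deadline=None)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(1)
        x = rng.normal(5, 2, 40)
        z0 = standardize_frame(pd.DataFrame({"x": x}), ["x"])["x"]
        z1 = standardize_frame(pd.DataFrame({"x": a * x + b}), ["x"])["x"]
        np.testing.assert_allclose(z0, z1, atol=1e-7)

    def test_zero_variance_names_the_variable(self):
        with pytest.raises(ValueError, match="flatvar"):
            standardize_frame(pd.DataFrame({"flatvar": [2.0, 2.0]}), ["flatvar"])


class TestRFModel:
    def test_outcome_on_itself_is_unit_beta(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"y": rng.normal(0, 3, 200)})
        df["x"] = df["y"]
        res = fit_rf_model(df, "x", "y")
        assert res.beta_std == pytest.approx(1.0, abs=1e-10)
        assert res.p < 1e-100

    def test_beta_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x": rng.normal(0, 1, 300)})
        df["y"] = -0.4 * df["x"] + rng.normal(0, 1, 300)
        r0 = fit_rf_model(df, "x", "y")
        df2 = pd.DataFrame({"x": 10 * df["x"] - 3, "y": 0.2 * df["y"] + 50})
        r1 = fit_rf_model(df2, "x", "y")
        assert r0.beta_std == pytest.approx(r1.beta_std, abs=1e-10)
        assert r0.ci_low <= r0.beta_std <= r0.ci_high

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [0.0, 1.0]})
        with pytest.raises(ValueError, match="complete rows"):
            fit_rf_model(df, "x", "y")


class TestBattery:
    def test_sign_recovery_across_the_battery(self):
        """Negative generating effects surface as negative standardized
        betas; the risk factor comes out positive."""
        cfg = null_config(600, seed=19)
        specs = dict(cfg.rf_specs)
        for name, sign in (("PA", -1.0), ("OPT", -1.0), ("NEU", 1.0)):
            specs[name] = specs[name].model_copy(
                update={"effect_on_sr_between": sign * 1.2})
        cfg = cfg.model_copy(update={"rf_specs": specs})
        base, weekly, _ = generate_cohort(cfg)
        w0 = weekly[weekly.t == 0]
        line = fit_normative_ols(w0["E"], w0["P"])
        data = compute_sr(line, w0).merge(base, on="participant_id")
        table = run_h1(data)
        betas = table.set_index("predictor")["beta_std"]
        ps = table.set_index("predictor")["p"]
        assert betas["PA"] < 0 and ps["PA"] < 1e-4
        assert betas["OPT"] < 0 and ps["OPT"] < 1e-4
        assert betas["NEU"] > 0 and ps["NEU"] < 1e-4
        assert abs(betas["CSS"]) < 0.15  # no effect injected

    def test_missing_rf_column_skipped(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"sr": rng.normal(0, 1, 50),
                           "style_PA": rng.normal(0, 1, 50)})
        table = run_h1(df)
        assert table["predictor"].tolist() == ["PA"]


class TestBaronKenny:
    def test_deterministic_chain(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 100)
        # m is x up to scale (plus a whiff of noise to keep x and m from
        # being perfectly collinear in the y model); y is exactly 0.5 m
        m = 2.0 * x + rng.normal(0, 1e-6, 100)
        df = pd.DataFrame({"x": x, "m": m, "y": 0.5 * m})
        res = baron_kenny(df, "x", "m", "y", mc_draws=10_000)
        assert res.a == pytest.approx(1.0, abs=1e-4)
        assert res.b == pytest.approx(1.0, abs=1e-3)
        assert res.c_prime == pytest.approx(0.0, abs=1e-3)
        assert res.indirect == res.a * res.b

    def test_full_mediation_path_algebra(self):
        """Noise-free mediation: c' = 0 and a*b = c exactly."""
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 500)
        q = rng.normal(0, 1, 500)
        m = 0.6 * x + 0.8 * q          # unit variance, corr(m, x) = 0.6
        y = 1.0 * m                     # full mediation, no direct path
        df = pd.DataFrame({"x": x, "m": m, "y": y})
        res = baron_kenny(df, "x", "m", "y", mc_draws=10_000)
        assert res.c_prime == pytest.approx(0.0, abs=1e-10)
        assert res.indirect == pytest.approx(res.c, abs=1e-10)

    def test_independent_mediator_gives_null_indirect(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"x": rng.normal(0, 1, 4000),
                           "m": rng.normal(0, 1, 4000),
                           "y": rng.normal(0, 1, 4000)})
        res = baron_kenny(df, "x", "m", "y", mc_draws=100_000)
        assert abs(res.a) < 0.05 and abs(res.indirect) < 0.01
        assert res.ci_low <= 0.0 <= res.ci_high


class TestDistributionOfProduct:
    def test_symmetric_null_interval(self):
        lo, hi = distribution_of_product_ci(0.0, 1.0, 0.0, 1.0, draws=2_000_000)
        assert abs(lo + hi) < 5e-3
        assert lo < 0 < hi

    def test_degenerate_limit_shrinks_to_the_product(self):
        lo, hi = distribution_of_product_ci(0.5, 1e-9, 0.4, 1e-9)
        assert lo == pytest.approx(0.2, abs=1e-6)
        assert hi == pytest.approx(0.2, abs=1e-6)

    def test_argument_exchange_symmetry(self):
        ci1 = distribution_of_product_ci(0.5, 0.1, 0.4, 0.2, draws=2_000_000, seed=1)
        ci2 = distribution_of_product_ci(0.4, 0.2, 0.5, 0.1, draws=2_000_000, seed=2)
        assert ci1[0] == pytest.approx(ci2[0], abs=2e-3)
        assert ci1[1] == pytest.approx(ci2[1], abs=2e-3)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(99)
        z = rng.normal(0.5, 0.1, 10_000_000) * rng.normal(0.4, 0.2, 10_000_000)
        oracle = np.quantile(z, [0.025, 0.975])
        lo, hi = distribution_of_product_ci(0.5, 0.1, 0.4, 0.2, seed=3)
        assert lo == pytest.approx(oracle[0], abs=2e-3)
        assert hi == pytest.approx(oracle[1], abs=2e-3)

    @pytest.mark.parametrize("bad", [
        dict(a=0.1, se_a=0.0, b=0.1, se_b=0.1),
        dict(a=0.1, se_a=0.1, b=0.1, se_b=-1.0),
        dict(a=np.inf, se_a=0.1, b=0.1, se_b=0.1),
    ])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            distribution_of_product_ci(**bad)

    def test_level_bounds(self):
        with pytest.raises(ValueError, match="level"):
            distribution_of_product_ci(0.1, 0.1, 0.1, 0.1, level=1.2)


class TestH2Recovery:
    def test_prospective_effect_recovered_in_sign(self):
        from srres.sr import average_sr, fit_normative_mixed
        cfg = calibrate_effect(null_config(400, seed=23), "REC", "h2", -0.3)
        base, weekly, _ = generate_cohort(cfg)
        line = fit_normative_mixed(weekly)
        scored = compute_sr(line, weekly)
        data = base.merge(average_sr(scored), on="participant_id")
        res = fit_rf_model(data, "style_REC", "mean_sr")
        assert res.beta_std < -0.15
        assert res.ci_low <= -0.3 <= res.ci_high or abs(res.beta_std + 0.3) < 0.1
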