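"""Within/between decomposition, weekly mixed models, ICC and mediation."""

import numpy as np
import pandas as pd
import pytest

from srres import generate_cohort
from srres.dynamics import (fit_autoregressive_followup, fit_contemporaneous,
                            fit_lagged, icc, multilevel_mediation_contemporaneous,
                            person_center)
from srres.sr import compute_sr, fit_normative_mixed
from srres.synth import calibrate_effect, null_config


def _scored(cfg):
    base, weekly, truth = generate_cohort(cfg)
    line = fit_normative_mixed(weekly)
    return base, compute_sr(line, weekly), truth


class TestPersonCenter:
    def test_triplet_example(self):
        df = pd.DataFrame({"participant_id": [1, 1, 1], "x": [1.0, 2.0, 3.0]})
        out = person_center(df, "x")
        assert (out["x_pm"] == 2.0).all()
        np.testing.assert_allclose(out["x_dm"], [-1.0, 0.0, 1.0])

    def test_constant_series(self):
        df = pd.DataFrame({"participant_id": [2] * 4, "x": [5.0] * 4})
        out = person_center(df, "x")
        assert (out["x_pm"] == 5.0).all()
        np.testing.assert_allclose(out["x_dm"], 0.0)

    def test_decomposition_exact_and_demeaned_sums_to_zero(self, default_cohort):
        _, _, weekly, _ = default_cohort
        out = person_center(weekly, "rf_PA")
        np.testing.assert_allclose(out["rf_PA_pm"] + out["rf_PA_dm"],
                                   out["rf_PA"], atol=1e-12)
        sums = out.groupby("participant_id")["rf_PA_dm"].sum()
        np.testing.assert_allclose(sums, 0.0, atol=1e-9)


class TestContemporaneous:
    def test_within_effect_recovered_between_near_zero(self):
        cfg = calibrate_effect(null_config(400, seed=41), "PA", "within", -0.3)
        _, scored, _ = _scored(cfg)
        res = fit_contemporaneous(scored, "rf_PA", "sr")
        assert res.within_ci[0] <= -0.3 <= res.within_ci[1]
        assert abs(res.between_beta) < 0.12
        assert res.n_participants == 400

    def test_between_effect_recovered_within_near_zero(self):
        cfg = calibrate_effect(null_config(400, seed=43), "PA", "between", -0.25)
        _, scored, _ = _scored(cfg)
        res = fit_contemporaneous(scored, "rf_PA", "sr")
        assert res.between_ci[0] <= -0.25 <= res.between_ci[1]
        assert abs(res.within_beta) < 0.1

    def test_constant_within_person_rf_flagged(self):
        cfg = null_config(80, seed=2)
        _, scored, _ = _scored(cfg)
        scored["rf_flat"] = scored.groupby("participant_id")["rf_PA"].transform("mean")
        with pytest.raises(ValueError, match="within-person"):
            fit_contemporaneous(scored, "rf_flat", "sr")


class TestLagged:
    def test_lagged_effect_recovered(self):
        cfg = calibrate_effect(null_config(400, seed=47), "PA", "lagged", -0.3)
        _, scored, _ = _scored(cfg)
        res = fit_lagged(scored, "rf_PA", "sr")
        assert res.within_ci[0] - 0.03 <= -0.3 <= res.within_ci[1] + 0.03
        assert res.within_beta < -0.2

    def test_contemporaneous_only_generator_shows_weak_lagged_signal(self):
        cfg = calibrate_effect(null_config(400, seed=53), "GSE", "within", -0.3)
        _, scored, _ = _scored(cfg)
        res = fit_lagged(scored, "rf_GSE", "sr")
        # leakage is bounded by the AR(1) persistence (~rho * within effect)
        assert abs(res.within_beta) < 0.18

    def test_pairs_never_bridge_dropped_weeks(self):
        cfg = null_config(120, seed=3)
        _, scored, _ = _scored(cfg)
        keep = scored[(scored.t != 2)]  # drop week 2 everywhere
        res = fit_lagged(keep, "rf_PA", "sr")
        # retained follow-up weeks {1, 3, 4, 5}: only (3,4) and (4,5) pair
        assert res.n_obs == 2 * 120

    def test_single_participant_pairing_rule(self):
        cfg = null_config(150, seed=4)
        _, scored, _ = _scored(cfg)
        trimmed = scored[~((scored.participant_id == 1)
                           & (scored.t.isin([2, 5])))]
        res_all = fit_lagged(scored, "rf_PA", "sr")
        res_trim = fit_lagged(trimmed, "rf_PA", "sr")
        # participant 1 retains weeks {1,3,4}: contributes only the (3,4) pair
        assert res_all.n_obs - res_trim.n_obs == 3


class TestAutoregressiveFollowup:
    def test_persistence_only_lagged_effect_vanishes_with_dv_control(self):
        """Exposure feeds the coping factor contemporaneously and persists
        by AR(1): the raw lagged exposure effect is significant, but
        controlling the factor's own week-t value removes it."""
        specs = dict(null_config(400).rf_specs)
        specs["BC"] = specs["BC"].model_copy(update={"ar1_coefficient": 0.85,
                                                     "exposure_effect_within": 0.06,
                                                     "between_sd": 0.0})
        # a longer panel keeps the known demeaning-feedback artifact of the
        # within estimator an order below the persistence-borne signal
        cfg = null_config(400, seed=61, rf_specs=specs, n_followups=15)
        _, weekly, _ = generate_cohort(cfg)
        raw = fit_lagged(weekly, "E", "rf_BC")
        adj = fit_autoregressive_followup(weekly, "E", "rf_BC")
        assert raw.within_p < 1e-4
        assert adj.within_p > 0.05
        assert abs(adj.within_beta) < abs(raw.within_beta) / 2
        assert adj.extra_terms["rf_BC"]["beta"] > 0.2  # the persistence itself

    def test_true_incremental_lagged_effect_survives_adjustment(self):
        cfg = calibrate_effect(null_config(600, seed=67), "PA", "lagged", -0.3)
        _, scored, _ = _scored(cfg)
        adj = fit_autoregressive_followup(scored, "rf_PA", "sr")
        assert adj.within_p < 0.01
        assert adj.within_beta < -0.15


class TestICC:
    def test_within_constant_data_near_one(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"participant_id": np.repeat(np.arange(100), 5)})
        df["x"] = rng.normal(0, 1, 100)[df.participant_id] + rng.normal(0, 1e-4, 500)
        assert icc(df, "x")["icc"] > 0.99

    def test_iid_data_near_zero(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"participant_id": np.repeat(np.arange(100), 5),
                           "x": rng.normal(0, 1, 500)})
        assert icc(df, "x")["icc"] < 0.05


class TestMultilevelMediation:
    def test_within_chain_recovered(self):
        """x -> m within-person chain (a = 0.35 correlation, b on m)
        yields the implied indirect effect within the interval."""
        base_cfg = null_config(500, seed=71)
        specs = dict(base_cfg.rf_specs)
        specs["PA"] = specs["PA"].model_copy(update={"effect_on_sr_within": -1.0})
        from srres.config import MediationSpec
        cfg = base_cfg.model_copy(update={
            "rf_specs": specs,
            "mediation_spec": MediationSpec(a=0.4, b=0.0, direct_c_prime=0.0)})
        _, scored, truth = _scored(cfg)
        res = multilevel_mediation_contemporaneous(scored, "rf_PSS", "rf_PA", "sr",
                                                   mc_draws=100_000)
        # the a path on the total-z scale rescales the latent correlation by
        # each factor's within-share of total SD
        pa, pss = cfg.rf_specs["PA"], cfg.rf_specs["PSS"]
        expected_a = 0.4 * (pa.within_sd / np.hypot(pa.between_sd, pa.within_sd)) \
            * (np.hypot(pss.between_sd, pss.within_sd) / pss.within_sd)
        assert res.a == pytest.approx(expected_a, abs=0.07)
        assert res.b < -0.1
        assert res.ci_low <= res.indirect <= res.ci_high
        assert res.significant

    def test_null_chain_interval_covers_zero(self):
        cfg = null_config(300, seed=73)
        _, scored, _ = _scored(cfg)
        res = multilevel_mediation_contemporaneous(scored, "rf_PSS", "rf_PA", "sr",
                                                   mc_draws=100_000)
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_noise_free_b_path_exact(self):
        """With SR built deterministically from the mediator's weekly
        deviation, the b path is exact and a*b matches the product."""
        cfg = null_config(200, seed=79)
        _, weekly, _ = generate_cohort(cfg)
        df = person_center(weekly[weekly.t >= 1].copy(), "rf_PA")
        rng = np.random.default_rng(0)
        df["sr"] = -0.5 * df["rf_PA_dm"] + rng.normal(0, 1e-6, len(df))
        res = multilevel_mediation_contemporaneous(df, "rf_PSS", "rf_PA", "sr",
                                                   mc_draws=10_000)
        sd_ratio = df["rf_PA"].std(ddof=1) / df["sr"].std(ddof=1)
        assert res.b == pytest.approx(-0.5 * sd_ratio, rel=1e-3)
        assert res.indirect == pytest.approx(res.a * res.b, abs=1e-12)
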