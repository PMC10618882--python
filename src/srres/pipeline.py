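"""End-to-end orchestration: simulate -> score -> prep -> SR -> analyze.

Runs the full outcome-based resilience analysis on a simulated or loaded
cohort and collects per-hypothesis result tables, the fitted normative
lines, sample-flow logs and a reproducibility manifest.  Also hosts the
two small report-level statistics: the Bonferroni-adjusted alpha for the
primary lagged hypotheses and the diagnosed-vs-not SR group contrast.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import dynamics, prep, regression, scoring, sr, synth
from .config import PipelineConfig, SimConfig

__all__ = ["bonferroni_threshold", "diagnosis_contrast", "run_pipeline",
           "ResultsBundle"]

logger = logging.getLogger(__name__)

#: Weekly RF modes entering the dynamic analyses, display order.
WEEKLY_RF_ORDER = ("PA", "PAC", "GSE", "PSS", "BC")
#: Primary lagged hypotheses (the two positive-appraisal modes).
PRIMARY_LAGGED_RFS = ("PA", "PAC")


def bonferroni_threshold(alpha: float, k: int) -> float:
    """Adjusted per-test alpha for k primary hypotheses (alpha / k)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    return alpha / k


def diagnosis_contrast(sr_scores=None, diagnosis=None, *, summary=None) -> dict:
    """Student's pooled-variance t contrast of SR between participants
    without and with a (past or present) mental-health diagnosis.

    Either pass raw ``sr_scores`` with a binary ``diagnosis`` flag, or a
    ``summary`` tuple ``(n0, mean0, sd0, n1, mean1, sd1)`` with group 0 =
    no diagnosis; the t statistic is then recomputed from the summaries
    alone.  Sign convention: t = (mean0 - mean1) / se, so a negative t
    means diagnosed participants score higher (worse) on SR.
    """
    if summary is not None:
        n0, m0, s0, n1, m1, s1 = summary
    else:
        sr_scores = np.asarray(sr_scores, dtype=float)
        diagnosis = np.asarray(diagnosis)
        g0, g1 = sr_scores[diagnosis == 0], sr_scores[diagnosis == 1]
        if len(g0) < 2 or len(g1) < 2:
            raise ValueError("each diagnosis group needs at least 2 observations")
        n0, m0, s0 = len(g0), g0.mean(), g0.std(ddof=1)
        n1, m1, s1 = len(g1), g1.mean(), g1.std(ddof=1)
    df = n0 + n1 - 2
    pooled_var = ((n0 - 1) * s0**2 + (n1 - 1) * s1**2) / df
    if pooled_var <= 0:
        raise ValueError("zero pooled variance; the contrast is degenerate")
    se = np.sqrt(pooled_var * (1.0 / n0 + 1.0 / n1))
    t = (m0 - m1) / se
    return {"t": float(t), "df": int(df), "p": float(2 * stats.t.sf(abs(t), df)),
            "n0": int(n0), "mean0": float(m0), "sd0": float(s0),
            "n1": int(n1), "mean1": float(m1), "sd1": float(s1)}


@dataclass
class ResultsBundle:
    """All outputs of one pipeline run."""

    h1: pd.DataFrame
    h2: pd.DataFrame
    h3: pd.DataFrame
    h4: pd.DataFrame
    h5: pd.DataFrame
    h5_autoregressive: pd.DataFrame
    mediation: pd.DataFrame
    iccs: pd.DataFrame
    cross_line: sr.NormativeLine
    long_line: sr.NormativeLine
    diagnosis: dict
    polynomial_checks: dict
    sample_flow: dict
    covariates: dict
    drop_log: pd.DataFrame = field(default_factory=pd.DataFrame)
    manifest: dict = field(default_factory=dict)

    def write(self, out_dir) -> dict[str, str]:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("h1", "h2", "h3", "h4", "h5", "h5_autoregressive",
                     "mediation", "iccs", "drop_log"):
            p = out / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths[name] = str(p)
        meta = {
            "cross_line": self.cross_line.to_dict(),
            "long_line": self.long_line.to_dict(),
            "diagnosis_contrast": self.diagnosis,
            "polynomial_checks": self.polynomial_checks,
            "sample_flow": self.sample_flow,
            "covariates": self.covariates,
        }
        for name, payload in (("normative_lines", meta), ("manifest", self.manifest)):
            p = out / f"{name}.json"
            p.write_text(json.dumps(payload, indent=2, default=str))
            paths[name] = str(p)
        return paths


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _mixed_rows(results: list[dynamics.MixedResult], labels: list[str]) -> pd.DataFrame:
    rows = []
    for label, res in zip(labels, results):
        d = res.to_dict()
        d["rf"] = label
        rows.append(d)
    frame = pd.DataFrame(rows)
    if len(frame):
        lead = ["rf", "within_beta", "within_se", "within_ci_low", "within_ci_high",
                "within_p", "between_beta", "between_se", "between_ci_low",
                "between_ci_high", "between_p", "n_obs", "n_participants"]
        frame = frame[lead + [c for c in frame.columns if c not in lead]]
    return frame


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    """Execute every stage of the analysis on one cohort.

    Stages: obtain data (simulate or load) -> score E/P -> spacing and
    completion filters -> Mahalanobis gate and normative lines (OLS at
    baseline, mixed for the pooled longitudinal weeks) -> SR scores ->
    covariate screens -> cross-sectional and prospective RF batteries and
    mediation -> weekly contemporaneous / lagged / exposure-to-RF mixed
    models with the autoregressive follow-up and ICCs.  Identical
    (config, seed) pairs reproduce the bundle exactly.
    """
    flow: dict = {}
    if config.sim is not None:
        sim_cfg = config.sim.model_copy(update={"seed": config.seed})
        baseline, weekly, _truth = synth.generate_cohort(sim_cfg)
    else:
        baseline, weekly, report = scoring.load_panel(config.baseline_path,
                                                      config.weekly_path)
        flow["load_warnings"] = report["warnings"]
    weekly = scoring.score_weekly_frame(weekly)
    weekly["date"] = pd.to_datetime(weekly["date"])
    flow["enrolled"] = int(baseline["participant_id"].nunique())

    # --- retention --------------------------------------------------------
    retained, drop_log = prep.filter_followup_spacing(weekly)
    long_ids = prep.filter_completion(retained, config.min_followups)
    flow["weekly_rows_retained"] = int(len(retained))
    flow["weekly_rows_dropped"] = int(len(drop_log))
    flow["longitudinal_n"] = int(len(long_ids))

    # --- cross-sectional normative line and SR ----------------------------
    base_week = retained[retained["t"] == 0].merge(baseline, on="participant_id")
    keep, _, _ = sr.mahalanobis_outliers(base_week["E"], base_week["P"])
    flow["cross_outliers_removed"] = int((~keep).sum())
    gated = base_week[keep]
    flow["cross_n"] = int(len(gated))
    cross_line = sr.fit_normative_ols(gated["E"], gated["P"],
                                      n_outliers_removed=int((~keep).sum()))
    base_scored = sr.compute_sr(cross_line, base_week, retain_mask=keep)
    poly_cross = sr.test_polynomial_term(gated, method="cross")

    # --- longitudinal normative line and weekly SR ------------------------
    long_weekly = retained[retained["participant_id"].isin(long_ids)].copy()
    keep_l, _, _ = sr.mahalanobis_outliers(long_weekly["E"], long_weekly["P"])
    flow["long_outliers_removed"] = int((~keep_l).sum())
    long_gated = long_weekly[keep_l]
    long_line = sr.fit_normative_mixed(long_gated,
                                       n_outliers_removed=int((~keep_l).sum()))
    long_scored = sr.compute_sr(long_line, long_weekly, retain_mask=keep_l)
    poly_long = sr.test_polynomial_term(long_gated, method="long")

    # --- covariate screens ------------------------------------------------
    cov_cross = prep.screen_covariates(base_scored.dropna(subset=["sr"]),
                                       config.candidate_covariates, "cross",
                                       alpha=prep.SCREEN_ALPHA)
    long_merged = long_scored.merge(baseline, on="participant_id")
    cov_long = prep.screen_covariates(long_merged.dropna(subset=["sr"]),
                                      config.candidate_covariates, "long",
                                      alpha=prep.SCREEN_ALPHA)

    # --- H1 + baseline mediation ------------------------------------------
    h1 = regression.run_h1(base_scored.dropna(subset=["sr"]), cov_cross)
    med_rows = []
    med_h1 = regression.baron_kenny(base_scored.dropna(subset=["sr"]),
                                    x="style_PSS", m="style_PA", y="sr",
                                    covariates=cov_cross,
                                    mc_draws=config.mc_draws, seed=config.seed)
    med_rows.append(dict(med_h1.to_dict(), hypothesis="cross_sectional"))

    # --- H2 + prospective mediation ----------------------------------------
    mean_sr = sr.average_sr(long_scored)
    h2_data = baseline.merge(base_scored[["participant_id", "sr"]],
                             on="participant_id", how="left")
    h2_data = h2_data.merge(mean_sr, on="participant_id", how="inner")
    h2 = regression.run_h2(h2_data.dropna(subset=["mean_sr"]), cov_long)
    med_h2 = regression.baron_kenny(h2_data.dropna(subset=["mean_sr"]),
                                    x="style_PSS", m="style_PA", y="mean_sr",
                                    covariates=cov_long,
                                    mc_draws=config.mc_draws, seed=config.seed + 1)
    med_rows.append(dict(med_h2.to_dict(), hypothesis="prospective"))

    # --- weekly dynamics ----------------------------------------------------
    dyn_data = long_merged
    weekly_rfs = [rf for rf in WEEKLY_RF_ORDER if f"rf_{rf}" in dyn_data.columns]
    h3_res, h4_res, h5_res, h5ar_res, icc_rows = [], [], [], [], []
    for rf in weekly_rfs:
        col = f"rf_{rf}"
        h3_res.append(dynamics.fit_contemporaneous(dyn_data, col, "sr", cov_long))
        h4_res.append(dynamics.fit_lagged(dyn_data, col, "sr", cov_long))
        h5_res.append(dynamics.fit_lagged(dyn_data, "E", col, cov_long))
        h5ar_res.append(dynamics.fit_autoregressive_followup(dyn_data, "E", col,
                                                             cov_long))
        icc_rows.append(dict(dynamics.icc(dyn_data[dyn_data["t"] >= 1], col), rf=rf))
    h3 = _mixed_rows(h3_res, weekly_rfs)
    h4 = _mixed_rows(h4_res, weekly_rfs)
    h5 = _mixed_rows(h5_res, weekly_rfs)
    h5ar = _mixed_rows(h5ar_res, weekly_rfs)

    alpha_primary = bonferroni_threshold(config.alpha, config.n_primary_hypotheses)
    if len(h4):
        h4["primary"] = h4["rf"].isin(PRIMARY_LAGGED_RFS)
        h4["alpha_applied"] = np.where(h4["primary"], alpha_primary, config.alpha)
        h4["passes_threshold"] = h4["within_p"] < h4["alpha_applied"]

    med_h3 = dynamics.multilevel_mediation_contemporaneous(
        dyn_data, x="rf_PSS", m="rf_PA", outcome="sr", covariates=cov_long,
        mc_draws=config.mc_draws, seed=config.seed + 2)
    med_rows.append(dict(med_h3.to_dict(), hypothesis="contemporaneous"))
    mediation = pd.DataFrame(med_rows)

    # --- diagnosis contrast -------------------------------------------------
    diag_data = base_scored.dropna(subset=["sr"])
    diag = diagnosis_contrast(diag_data["sr"], diag_data["diagnosis"])

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "config": config.model_dump(mode="json"),
        "alpha_primary": alpha_primary,
    }
    return ResultsBundle(
        h1=h1, h2=h2, h3=h3, h4=h4, h5=h5, h5_autoregressive=h5ar,
        mediation=mediation, iccs=pd.DataFrame(icc_rows),
        cross_line=cross_line, long_line=long_line, diagnosis=diag,
        polynomial_checks={"cross": poly_cross, "long": poly_long},
        sample_flow=flow,
        covariates={"cross": cov_cross.__dict__, "long": cov_long.__dict__},
        drop_log=drop_log, manifest=manifest)
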