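"""Synthetic intensive-longitudinal cohort generator with known ground truth.

The generator emulates the statistical structure of a weekly stress-survey
panel: one baseline record per participant (demographics, candidate
covariates, resilience-factor "style" scores) and one record per retained
participant-week (stressor severity items, symptom items, weekly RF
"modes", assessment dates with scheduling jitter, monotone attrition).

Because every latent component is drawn explicitly, the implied population
quantities -- the normative exposure--symptom line, per-factor intraclass
correlations, standardized cross-sectional / prospective / contemporaneous /
lagged effects on stressor reactivity, and mediation paths -- are available
in closed form (:func:`implied_standardized_effect`,
:func:`implied_sr_sd`), which is what makes parameter-recovery and coverage
studies of the downstream estimators possible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import MediationSpec, RFSpec, SimConfig, default_rf_specs

__all__ = [
    "WeekState",
    "GroundTruth",
    "generate_cohort",
    "stressor_severity_draw",
    "e_moments",
    "implied_sr_sd",
    "implied_standardized_effect",
    "calibrate_effect",
    "icc_target",
    "null_config",
]

EffectKind = Literal["h1", "h2", "within", "between", "lagged"]

_SEVERITY_VALUES = np.arange(1, 6)


# ---------------------------------------------------------------------------
# closed-form moments of the generating model
# ---------------------------------------------------------------------------

def e_moments(config: SimConfig) -> dict[str, float]:
    """Closed-form moments of weekly stressor exposure E.

    E is a sum of ``k`` items, each ``Bernoulli(pi_i) * severity`` with the
    per-person occurrence probability ``pi_i = p + q_i``,
    ``q_i ~ N(0, occurrence_between_sd^2)`` (clipping ignored, which is
    accurate for the default parameter region).
    """
    k = config.n_stressor_items
    probs = np.asarray(config.severity_probs)
    m = float(probs @ _SEVERITY_VALUES)
    m2 = float(probs @ _SEVERITY_VALUES**2)
    p = config.occurrence_prob
    sq2 = config.occurrence_between_sd**2
    mean = k * p * m
    var_between = k**2 * m**2 * sq2
    var_within = k * (p * m2 - (p**2 + sq2) * m**2)
    var_total = var_between + var_within
    return {
        "mean": mean,
        "var_between": var_between,
        "var_within": var_within,
        "var_total": var_total,
        "second_moment": var_total + mean**2,
        "severity_mean": m,
        "severity_second_moment": m2,
    }


def icc_target(spec: RFSpec) -> float:
    """Intraclass correlation implied by a factor's variance components."""
    b2, w2 = spec.between_sd**2, spec.within_sd**2
    if b2 + w2 == 0:
        return float("nan")
    return b2 / (b2 + w2)


def _effective_between_effects(config: SimConfig) -> dict[str, float]:
    eb = {name: s.effect_on_sr_between for name, s in config.rf_specs.items()}
    med = config.mediation_spec
    if med is not None:
        eb[med.m] = med.b
        eb[med.x] = med.direct_c_prime
    return eb


def _partner(config: SimConfig, rf: str) -> tuple[Optional[str], float]:
    """Mediation partner of ``rf`` and the latent correlation ``a``."""
    med = config.mediation_spec
    if med is None:
        return None, 0.0
    if rf == med.x:
        return med.m, med.a
    if rf == med.m:
        return med.x, med.a
    return None, 0.0


def _within_process_basis(config: SimConfig) -> dict[str, dict[str, tuple[float, float]]]:
    """Express each weekly RF's standardized within-process as a linear
    combination of independent unit-variance AR(1) basis processes.

    Returns ``{rf: {basis_key: (weight, rho)}}``.  The mediation pair
    shares the predictor's basis process, which encodes the within-person
    correlation ``a`` between the two factors.
    """
    med = config.mediation_spec
    basis: dict[str, dict[str, tuple[float, float]]] = {}
    for name, spec in config.rf_specs.items():
        if not spec.weekly:
            continue
        if med is not None and name == med.m:
            a = med.a
            rho_x = config.rf_specs[med.x].ar1_coefficient
            basis[name] = {
                med.x: (a, rho_x),
                f"{name}_perp": (np.sqrt(1 - a**2), spec.ar1_coefficient),
            }
        else:
            basis[name] = {name: (1.0, spec.ar1_coefficient)}
    return basis


def _within_contribution_cov(config: SimConfig, times: np.ndarray) -> np.ndarray:
    """Covariance matrix of the summed within-person RF contribution to SR
    across the given assessment indices (lagged terms active for t >= 1)."""
    basis = _within_process_basis(config)
    procs: dict[str, float] = {}
    alpha: dict[str, float] = {}
    beta: dict[str, float] = {}
    for name, spec in config.rf_specs.items():
        if not spec.weekly:
            continue
        for key, (wgt, rho) in basis[name].items():
            procs[key] = rho
            alpha[key] = alpha.get(key, 0.0) + spec.effect_on_sr_within * wgt
            beta[key] = beta.get(key, 0.0) + spec.lagged_effect_on_sr * wgt
    T = len(times)
    cov = np.zeros((T, T))
    for key, rho in procs.items():
        a, b = alpha[key], beta[key]
        for i, s in enumerate(times):
            for j, t in enumerate(times):
                c = a * a * rho ** abs(s - t)
                if s >= 1 and t >= 1:
                    c += b * b * rho ** abs(s - t)
                if t >= 1:
                    c += a * b * rho ** abs(s - t + 1)
                if s >= 1:
                    c += a * b * rho ** abs(s - t - 1)
                cov[i, j] += c
    return cov


def implied_sr_sd(config: SimConfig, scope: str = "weekly") -> float:
    """Population SD of the true stressor-reactivity deviation SR*.

    ``scope``: ``"weekly"`` (a follow-up week, lagged contributions
    active), ``"baseline"`` (t=0, no lagged terms) or ``"mean"`` (the
    per-participant mean over the follow-up weeks, as used for prospective
    analyses).  Assumes full retention; attrition-free recovery designs.
    """
    em = e_moments(config)
    p = config.diagnosis_prevalence
    base = (config.sd_random_intercept**2
            + config.diagnosis_sr_shift**2 * p * (1 - p))
    eb = _effective_between_effects(config)
    bvar = sum(e**2 for e in eb.values())
    med = config.mediation_spec
    if med is not None:
        bvar += 2 * med.a * eb[med.x] * eb[med.m]
    T = config.n_followups
    if scope == "baseline":
        wcov = _within_contribution_cov(config, np.array([0]))
        var = base + config.sd_random_slope**2 * em["second_moment"] + bvar \
            + wcov[0, 0] + config.residual_sd**2
    elif scope == "weekly":
        wcov = _within_contribution_cov(config, np.array([1]))
        var = base + config.sd_random_slope**2 * em["second_moment"] + bvar \
            + wcov[0, 0] + config.residual_sd**2
    elif scope == "mean":
        times = np.arange(1, T + 1)
        wcov = _within_contribution_cov(config, times)
        ebar2 = em["mean"]**2 + em["var_between"] + em["var_within"] / T
        var = base + config.sd_random_slope**2 * ebar2 + bvar \
            + wcov.mean() + config.residual_sd**2 / T
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return float(np.sqrt(var))


def _marginal_within_slopes(config: SimConfig, rf: str) -> tuple[float, float]:
    """(contemporaneous, lagged) marginal slope of SR on the focal factor's
    standardized within-deviation, including mediation-partner leakage."""
    spec = config.rf_specs[rf]
    partner, a = _partner(config, rf)
    rho = spec.ar1_coefficient
    s_now = spec.effect_on_sr_within + rho * spec.lagged_effect_on_sr
    s_lag = spec.lagged_effect_on_sr + rho * spec.effect_on_sr_within
    if partner is not None and config.rf_specs[partner].weekly:
        o = config.rf_specs[partner]
        s_now += a * (o.effect_on_sr_within + rho * o.lagged_effect_on_sr)
        s_lag += a * (o.lagged_effect_on_sr + rho * o.effect_on_sr_within)
    return s_now, s_lag


def implied_standardized_effect(config: SimConfig, rf: str, kind: EffectKind) -> float:
    """True fully standardized association targeted by each analysis.

    kind:
      - ``"h1"``: baseline SR regressed on the baseline style score.
      - ``"h2"``: mean follow-up SR regressed on the baseline style score.
      - ``"within"`` / ``"between"``: the demeaned / person-mean
        coefficient of the contemporaneous weekly mixed model, under the
        package's standardization convention (outcome and raw predictor
        z-scored on the analysis rows before decomposition).
      - ``"lagged"``: the demeaned coefficient of the one-week-lagged model.

    Exact for the generating model up to finite-sample noise; the within /
    lagged formulas are probability limits that treat person-mean
    estimation error as independent of the demeaned predictor, which holds
    in the single-effect designs used by the recovery suites.
    """
    spec = config.rf_specs[rf]
    eb = _effective_between_effects(config)
    partner, a = _partner(config, rf)
    eb_marg = eb[rf] + (a * eb[partner] if partner is not None else 0.0)
    sb, sw = spec.between_sd, spec.within_sd

    if kind in ("h1", "h2"):
        style_sd = float(np.hypot(sb, spec.style_noise_sd))
        if style_sd == 0:
            raise ValueError(f"{rf}: style score has zero variance")
        cov = eb_marg * sb
        sd_y = implied_sr_sd(config, "baseline" if kind == "h1" else "mean")
        return cov / (style_sd * sd_y)

    if not spec.weekly:
        raise ValueError(f"{rf} is not a weekly mode")
    sd_tot = float(np.hypot(sb, sw))
    sd_y = implied_sr_sd(config, "weekly")
    s_now, s_lag = _marginal_within_slopes(config, rf)
    if kind == "within":
        return s_now * sd_tot / (sw * sd_y)
    if kind == "lagged":
        return s_lag * sd_tot / (sw * sd_y)
    if kind == "between":
        T = config.n_followups
        rho = spec.ar1_coefficient
        lags = np.abs(np.subtract.outer(np.arange(T), np.arange(T)))
        v_wbar = sw**2 * np.mean(rho**lags)
        cov = eb_marg * sb + s_now * v_wbar / sw
        return cov * sd_tot / ((sb**2 + v_wbar) * sd_y)
    raise ValueError(f"unknown effect kind {kind!r}")


def null_config(n_participants: int, **overrides) -> SimConfig:
    """A global-null generating model for calibration and error-rate studies.

    Keeps the default variance structure (normative line, RF variance
    components, exposure process) but zeroes every RF -> SR effect, the
    mediation chain, the diagnosis shift and the random-slope dispersion,
    and emits continuous symptom scores (no item quantization) so that the
    closed-form effect algebra is exact.  Attrition and visit jitter are
    off by default; any field can still be overridden.
    """
    specs = {
        name: spec.model_copy(update={"effect_on_sr_between": 0.0,
                                      "effect_on_sr_within": 0.0,
                                      "lagged_effect_on_sr": 0.0})
        for name, spec in default_rf_specs().items()
    }
    base = dict(
        n_participants=n_participants,
        rf_specs=specs,
        mediation_spec=None,
        sd_random_slope=0.0,
        diagnosis_sr_shift=0.0,
        dropout_prob_per_week=0.0,
        date_jitter_days=0,
        quantize_items=False,
    )
    base.update(overrides)
    return SimConfig(**base)


_KIND_FIELD = {
    "h1": "effect_on_sr_between",
    "h2": "effect_on_sr_between",
    "between": "effect_on_sr_between",
    "within": "effect_on_sr_within",
    "lagged": "lagged_effect_on_sr",
}


def calibrate_effect(config: SimConfig, rf: str, kind: EffectKind,
                     target_beta: float, bound: float = 60.0) -> SimConfig:
    """Return a config whose raw effect for ``rf`` is set so that the true
    standardized association of the given kind equals ``target_beta``.

    Solves the self-consistency between the raw effect and the SR scale it
    itself inflates.  Refuses to calibrate a between-person effect that the
    mediation spec overrides.
    """
    fieldname = _KIND_FIELD[kind]
    med = config.mediation_spec
    if med is not None and fieldname == "effect_on_sr_between" and rf in (med.x, med.m):
        raise ValueError(f"{rf}: between effect is governed by mediation_spec; "
                         "remove it before calibrating")

    def beta_at(value: float) -> float:
        specs = dict(config.rf_specs)
        specs[rf] = specs[rf].model_copy(update={fieldname: value})
        trial = config.model_copy(update={"rf_specs": specs})
        return implied_standardized_effect(trial, rf, kind) - target_beta

    solution = brentq(beta_at, -bound, bound, xtol=1e-10)
    specs = dict(config.rf_specs)
    specs[rf] = specs[rf].model_copy(update={fieldname: float(solution)})
    return config.model_copy(update={"rf_specs": specs})


# ---------------------------------------------------------------------------
# ground truth container
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Generating quantities of one simulated cohort.

    ``random_effects`` holds one row per generated participant (the
    person-level latents); ``effects`` tabulates the effective per-factor
    raw effects and ICC targets; ``mediation`` the true path coefficients
    on the standardized-latent scale.
    """

    ep_intercept: float
    ep_slope: float
    effects: pd.DataFrame
    mediation: Optional[dict] = None
    random_effects: pd.DataFrame = field(default_factory=pd.DataFrame)
    config: Optional[SimConfig] = None

    def to_json(self) -> str:
        payload = {
            "ep_intercept": self.ep_intercept,
            "ep_slope": self.ep_slope,
            "effects": self.effects.to_dict(orient="records"),
            "mediation": self.mediation,
            "random_effects": self.random_effects.to_dict(orient="records"),
            "config": None if self.config is None else self.config.model_dump(mode="json"),
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

@dataclass
class WeekState:
    """Per-participant-week state consumed by :func:`stressor_severity_draw`."""

    rng: np.random.Generator
    occurrence_prob: float


def stressor_severity_draw(config: SimConfig, week_state: WeekState) -> np.ndarray:
    """Draw one week's stressor severity vector.

    Each of the ``n_stressor_items`` items independently occurs with the
    week state's occurrence probability; an item that occurred draws an
    integer burden severity in {1..5} from ``severity_probs``, an item that
    did not is coded 0 ("did not happen").
    """
    rng = week_state.rng
    k = config.n_stressor_items
    occurred = rng.random(k) < week_state.occurrence_prob
    sev = rng.choice(_SEVERITY_VALUES, size=k, p=np.asarray(config.severity_probs))
    return np.where(occurred, sev, 0).astype(np.int64)


def _ar1_unit(rng: np.random.Generator, n: int, T1: int, rho: float) -> np.ndarray:
    """(n, T1) stationary AR(1) draws with unit marginal variance."""
    z = np.empty((n, T1))
    z[:, 0] = rng.standard_normal(n)
    c = np.sqrt(1.0 - rho**2)
    for t in range(1, T1):
        z[:, t] = rho * z[:, t - 1] + c * rng.standard_normal(n)
    return z


def _distribute_ghq_items(p_int: np.ndarray) -> np.ndarray:
    """Split integer symptom totals in [0, 36] into 12 items in {0..3}."""
    base, rem = np.divmod(p_int, 12)
    items = np.repeat(base[..., None], 12, axis=-1)
    bump = np.arange(12) < rem[..., None]
    return (items + bump).astype(np.int64)


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (baseline_table, weekly_table, ground_truth).

    The weekly table is long format, one row per retained participant-week
    (assessment index ``t``; 0 = baseline), with integer stressor severity
    items ``s01..sKK``, symptom items ``ghq01..ghq12`` (when
    ``quantize_items``; otherwise a continuous ``P``), convenience totals
    ``E`` and ``P``, and weekly RF mode columns ``rf_<name>``.  The
    baseline table has one row per participant with demographics, candidate
    covariates and style scores ``style_<name>`` for all factors.
    Identical (config, seed) pairs yield identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n, T = config.n_participants, config.n_followups
    T1 = T + 1
    med = config.mediation_spec

    # -- demographics and candidate covariates -----------------------------
    age = np.clip(rng.normal(32.0, 12.0, n), 18, 71).round().astype(np.int64)
    gender = rng.choice(["female", "male"], size=n, p=[0.77, 0.23])
    language = rng.choice(["de", "nl", "pl", "it", "en"], size=n,
                          p=[0.65, 0.15, 0.09, 0.07, 0.04])
    education = np.clip(rng.normal(17.5, 3.3, n), 8, 33).round(1)
    general_health = rng.choice([1, 2, 3, 4, 5], size=n, p=[0.15, 0.40, 0.30, 0.10, 0.05])
    risk_group = rng.choice(["no", "yes", "not_sure"], size=n, p=[0.78, 0.09, 0.13])
    opinion = rng.choice([1, 2, 3, 4, 5], size=n, p=[0.03, 0.05, 0.17, 0.40, 0.35])
    diagnosis = (rng.random(n) < config.diagnosis_prevalence).astype(np.int64)

    # -- person-level latents ---------------------------------------------
    d0 = rng.normal(0.0, config.sd_random_intercept, n)
    d1 = rng.normal(0.0, config.sd_random_slope, n)
    pi = np.clip(config.occurrence_prob + rng.normal(0.0, config.occurrence_between_sd, n),
                 0.02, 0.98)

    z_u: dict[str, np.ndarray] = {}
    order = list(config.rf_specs)
    if med is not None:
        zx = rng.standard_normal(n)
        z_u[med.x] = zx
        z_u[med.m] = med.a * zx + np.sqrt(1 - med.a**2) * rng.standard_normal(n)
    for name in order:
        if name not in z_u:
            z_u[name] = rng.standard_normal(n)
    u = {name: config.rf_specs[name].between_sd * z_u[name] for name in order}

    # -- stressor exposure -------------------------------------------------
    k = config.n_stressor_items
    occurred = rng.random((n, T1, k)) < pi[:, None, None]
    sev = rng.choice(_SEVERITY_VALUES, size=(n, T1, k),
                     p=np.asarray(config.severity_probs))
    severities = np.where(occurred, sev, 0).astype(np.int64)
    E = severities.sum(axis=2)

    em = e_moments(config)
    m_sev = em["severity_mean"]
    per_person_var = k * (pi * em["severity_second_moment"] - pi**2 * m_sev**2)
    zE_within = (E - (k * pi * m_sev)[:, None]) / np.sqrt(per_person_var)[:, None]

    # -- within-person RF processes ---------------------------------------
    z_w: dict[str, np.ndarray] = {}
    weekly_names = [nm for nm in order if config.rf_specs[nm].weekly]
    if med is not None:
        rho_x = config.rf_specs[med.x].ar1_coefficient
        zxw = _ar1_unit(rng, n, T1, rho_x)
        zperp = _ar1_unit(rng, n, T1, config.rf_specs[med.m].ar1_coefficient)
        z_w[med.x] = zxw
        z_w[med.m] = med.a * zxw + np.sqrt(1 - med.a**2) * zperp
    for name in weekly_names:
        if name not in z_w:
            z_w[name] = _ar1_unit(rng, n, T1, config.rf_specs[name].ar1_coefficient)

    w: dict[str, np.ndarray] = {}
    for name in weekly_names:
        spec = config.rf_specs[name]
        if spec.exposure_effect_within != 0.0:
            # exposure feeds the AR(1) innovation, so E_t reaches future RF
            # values only through the factor's own persistence
            rho = spec.ar1_coefficient
            wn = np.empty((n, T1))
            innov_sd = spec.within_sd * np.sqrt(1 - rho**2)
            wn[:, 0] = spec.within_sd * rng.standard_normal(n) \
                + spec.exposure_effect_within * zE_within[:, 0]
            for t in range(1, T1):
                wn[:, t] = rho * wn[:, t - 1] + innov_sd * rng.standard_normal(n) \
                    + spec.exposure_effect_within * zE_within[:, t]
            w[name] = wn
        else:
            w[name] = spec.within_sd * z_w[name]

    # -- stressor reactivity and symptoms ----------------------------------
    eb = _effective_between_effects(config)
    sr_true = (d0[:, None] + d1[:, None] * E
               + config.diagnosis_sr_shift
               * (diagnosis - config.diagnosis_prevalence)[:, None]
               + rng.normal(0.0, config.residual_sd, (n, T1)))
    for name in order:
        sr_true += eb[name] * z_u[name][:, None]
    for name in weekly_names:
        spec = config.rf_specs[name]
        if spec.within_sd > 0:
            zw = w[name] / spec.within_sd
            sr_true += spec.effect_on_sr_within * zw
            if spec.lagged_effect_on_sr != 0.0:
                lagged = np.zeros_like(zw)
                lagged[:, 1:] = zw[:, :-1]
                sr_true += spec.lagged_effect_on_sr * lagged

    P_cont = config.ep_intercept + config.ep_slope * E + sr_true
    if config.quantize_items:
        P_int = np.clip(np.rint(P_cont), 0, 36).astype(np.int64)
        ghq = _distribute_ghq_items(P_int)
        P_obs = P_int
    else:
        ghq = None
        P_obs = P_cont

    # -- retention and schedule --------------------------------------------
    alive = np.ones((n, T1), dtype=bool)
    for t in range(1, T1):
        alive[:, t] = alive[:, t - 1] & (rng.random(n) >= config.dropout_prob_per_week)

    j = config.date_jitter_days
    jitter = np.zeros((n, T1), dtype=np.int64)
    if j > 0:
        jitter[:, 1:] = rng.integers(-j, j + 1, size=(n, T))
    offsets = 7 * np.arange(T1)[None, :] + jitter

    # -- assemble tables ----------------------------------------------------
    pid = np.arange(1, n + 1)
    rows_i, rows_t = np.nonzero(alive)
    base_date = pd.Timestamp(config.baseline_date)
    dates = base_date + pd.to_timedelta(offsets[rows_i, rows_t], unit="D")

    weekly = pd.DataFrame({"participant_id": pid[rows_i], "t": rows_t, "date": dates})
    sev_cols = {f"s{i + 1:02d}": severities[rows_i, rows_t, i] for i in range(k)}
    weekly = pd.concat([weekly, pd.DataFrame(sev_cols, index=weekly.index)], axis=1)
    if ghq is not None:
        ghq_cols = {f"ghq{i + 1:02d}": ghq[rows_i, rows_t, i] for i in range(12)}
        weekly = pd.concat([weekly, pd.DataFrame(ghq_cols, index=weekly.index)], axis=1)
    weekly["E"] = E[rows_i, rows_t]
    weekly["P"] = P_obs[rows_i, rows_t]
    for name in weekly_names:
        weekly[f"rf_{name}"] = (config.rf_specs[name].mean + u[name][:, None]
                                + w[name])[rows_i, rows_t]

    baseline = pd.DataFrame({
        "participant_id": pid,
        "age": age,
        "gender": gender,
        "language": language,
        "education": education,
        "general_health": general_health,
        "risk_group": risk_group,
        "opinion_measures": opinion,
        "diagnosis": diagnosis,
    })
    for name in order:
        spec = config.rf_specs[name]
        style = spec.mean + u[name]
        if spec.style_noise_sd > 0:
            style = style + rng.normal(0.0, spec.style_noise_sd, n)
        baseline[f"style_{name}"] = style

    effects = pd.DataFrame({
        "rf": order,
        "weekly": [config.rf_specs[nm].weekly for nm in order],
        "between_effect": [eb[nm] for nm in order],
        "within_effect": [config.rf_specs[nm].effect_on_sr_within for nm in order],
        "lagged_effect": [config.rf_specs[nm].lagged_effect_on_sr for nm in order],
        "icc_target": [icc_target(config.rf_specs[nm]) for nm in order],
    })
    mediation = None
    if med is not None:
        mediation = {"x": med.x, "m": med.m, "a": med.a, "b": med.b,
                     "c_prime": med.direct_c_prime, "indirect": med.a * med.b}
    re_frame = pd.DataFrame({"participant_id": pid, "d0": d0, "d1": d1,
                             "occurrence_prob": pi})
    for name in order:
        re_frame[f"u_{name}"] = u[name]

    truth = GroundTruth(ep_intercept=config.ep_intercept, ep_slope=config.ep_slope,
                        effects=effects, mediation=mediation,
                        random_effects=re_frame, config=config)
    return baseline, weekly, truth


def write_cohort(baseline: pd.DataFrame, weekly: pd.DataFrame, truth: GroundTruth,
                 out_dir) -> dict[str, str]:
    """Write the cohort as UTF-8 CSV (ISO dates) plus a ground-truth JSON."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "baseline": str(out / "baseline.csv"),
        "weekly": str(out / "weekly.csv"),
        "ground_truth": str(out / "ground_truth.json"),
    }
    baseline.to_csv(paths["baseline"], index=False)
    wk = weekly.copy()
    wk["date"] = pd.to_datetime(wk["date"]).dt.strftime("%Y-%m-%d")
    wk.to_csv(paths["weekly"], index=False)
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        fh.write(truth.to_json())
    return paths
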