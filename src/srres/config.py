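"""Configuration models for the synthetic cohort generator and the pipeline.

All stochastic behaviour of the package is determined by a validated,
serializable configuration object plus a seed.  :class:`SimConfig` describes
the generating model of the synthetic cohort (exposure process, normative
exposure--symptom line, resilience-factor dynamics, attrition, scheduling
jitter); :class:`PipelineConfig` wraps a full simulate -> score -> prep ->
score-reactivity -> analyze run.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = ["RFSpec", "MediationSpec", "SimConfig", "PipelineConfig", "default_rf_specs"]


class RFSpec(BaseModel):
    """Generating parameters for a single resilience factor (RF).

    A weekly RF mode is generated as ``mean + u_i + w_it`` with a stable
    person component ``u_i ~ N(0, between_sd^2)`` and a stationary AR(1)
    within-person fluctuation ``w_it`` with marginal SD ``within_sd`` and
    lag-1 autocorrelation ``ar1_coefficient``.  The baseline "style"
    measurement of the same factor is ``mean + u_i`` plus optional
    independent measurement noise (``style_noise_sd``).

    Effects on stressor reactivity (SR) are expressed in symptom units per
    1 SD of the respective latent component: ``effect_on_sr_between`` acts
    through ``u_i / between_sd``, ``effect_on_sr_within`` through
    ``w_it / within_sd`` (same week), and ``lagged_effect_on_sr`` through
    ``w_i,t-1 / within_sd`` (previous week; inactive at baseline).

    ``exposure_effect_within`` feeds the standardized within-person
    deviation of stressor exposure E into the AR(1) innovation of the RF,
    so past exposure propagates into future RF values purely through the
    RF's own persistence.  It inflates the marginal within-person variance
    and is meant for targeted simulation experiments, not as a default.
    """

    mean: float = 3.0
    between_sd: float = Field(0.8, ge=0)
    within_sd: float = Field(0.5, ge=0)
    ar1_coefficient: float = Field(0.3, gt=-1.0, lt=1.0)
    effect_on_sr_between: float = 0.0
    effect_on_sr_within: float = 0.0
    lagged_effect_on_sr: float = 0.0
    exposure_effect_within: float = 0.0
    style_noise_sd: float = Field(0.0, ge=0)
    weekly: bool = True


class MediationSpec(BaseModel):
    """Generating structure for the mediated x -> m -> SR chain.

    ``a`` is the correlation between the between-person latents of the
    predictor RF ``x`` and the mediator RF ``m`` (also applied to their
    within-person AR(1) processes).  ``b`` and ``direct_c_prime`` override
    the between-person SR effects of ``m`` and ``x`` respectively, so that
    in a Baron--Kenny decomposition on person-level data the true paths are
    exactly a, b and c' (and the true indirect effect is a*b on the
    standardized-latent scale).
    """

    x: str = "PSS"
    m: str = "PA"
    a: float = Field(0.35, gt=-1.0, lt=1.0)
    b: float = -1.0
    direct_c_prime: float = -0.6


def default_rf_specs() -> dict[str, RFSpec]:
    """Default resilience-factor battery.

    Nine factors mirroring a typical resilience survey: positive appraisal
    style (PA), pandemic-specific positive appraisal (PAC), optimism (OPT),
    general self-efficacy (GSE), stress recovery (REC), perceived social
    support (PSS), change in social support (CSS), behavioral coping (BC)
    and neuroticism (NEU, a risk factor with a positive SR effect).  Five
    are measured weekly as modes; the others at baseline only.  Variance
    ratios put the implied intraclass correlations in the 0.64--0.85 band.
    """
    return {
        "PA": RFSpec(between_sd=0.90, within_sd=0.50, effect_on_sr_between=-1.0,
                     effect_on_sr_within=-0.50),
        "PAC": RFSpec(between_sd=0.80, within_sd=0.60, effect_on_sr_between=-0.80,
                      effect_on_sr_within=-0.35),
        "OPT": RFSpec(between_sd=0.90, effect_on_sr_between=-1.10, weekly=False),
        "GSE": RFSpec(between_sd=0.90, within_sd=0.45, effect_on_sr_between=-0.90,
                      effect_on_sr_within=-0.50),
        "REC": RFSpec(between_sd=0.85, effect_on_sr_between=-0.90, weekly=False),
        "PSS": RFSpec(between_sd=1.00, within_sd=0.45, effect_on_sr_between=-0.60),
        "CSS": RFSpec(between_sd=0.80, effect_on_sr_between=0.0, weekly=False),
        "BC": RFSpec(between_sd=0.85, within_sd=0.55, effect_on_sr_between=-0.30),
        "NEU": RFSpec(between_sd=0.90, effect_on_sr_between=1.00, weekly=False),
    }


class SimConfig(BaseModel):
    """Full generating model for a synthetic intensive-longitudinal cohort.

    The symptom score P for participant i in week t follows

    ``P_it = ep_intercept + ep_slope * E_it + d0_i + d1_i * E_it + SR*_it``

    where ``(d0_i, d1_i)`` are independent normal random intercept/slope
    deviations from the normative exposure--symptom line and ``SR*_it``
    collects the RF contributions, a diagnosis shift and week-level noise.
    Stressor exposure E is the sum of ``n_stressor_items`` integer severity
    ratings in {0..5}; each item occurs with a per-person probability and,
    if it occurred, draws a severity in {1..5} from ``severity_probs``.
    """

    n_participants: int = Field(..., ge=1)
    n_followups: int = Field(5, ge=1)
    n_stressor_items: int = Field(40, ge=1)

    ep_intercept: float = 8.0
    ep_slope: float = 0.12
    sd_random_intercept: float = Field(2.0, ge=0)
    sd_random_slope: float = Field(0.015, ge=0)
    residual_sd: float = Field(3.0, ge=0)

    rf_specs: dict[str, RFSpec] = Field(default_factory=default_rf_specs)
    mediation_spec: Optional[MediationSpec] = Field(default_factory=MediationSpec)

    occurrence_prob: float = Field(0.35, gt=0.0, lt=1.0)
    occurrence_between_sd: float = Field(0.08, ge=0)
    severity_probs: tuple[float, float, float, float, float] = (0.2, 0.2, 0.2, 0.2, 0.2)

    dropout_prob_per_week: float = Field(0.07, ge=0.0, le=1.0)
    date_jitter_days: int = Field(1, ge=0)
    baseline_date: dt.date = dt.date(2020, 4, 20)

    diagnosis_prevalence: float = Field(0.33, ge=0.0, le=1.0)
    diagnosis_sr_shift: float = 1.7

    quantize_items: bool = True
    seed: int = 0

    @field_validator("severity_probs")
    @classmethod
    def _probs_valid(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if any(p < 0 for p in v):
            raise ValueError("severity_probs must be nonnegative")
        if abs(sum(v) - 1.0) > 1e-8:
            raise ValueError("severity_probs must sum to 1")
        return v

    @model_validator(mode="after")
    def _mediation_refs_exist(self) -> "SimConfig":
        if self.mediation_spec is not None:
            for role in (self.mediation_spec.x, self.mediation_spec.m):
                if role not in self.rf_specs:
                    raise ValueError(f"mediation_spec references unknown RF {role!r}")
            mx, mm = self.mediation_spec.x, self.mediation_spec.m
            if not (self.rf_specs[mx].weekly and self.rf_specs[mm].weekly):
                raise ValueError("mediation_spec RFs must be weekly modes")
        return self


class PipelineConfig(BaseModel):
    """Configuration of a full end-to-end pipeline run.

    ``sim`` is optional: when absent, ``baseline_path``/``weekly_path``
    must point at CSV tables with the layout written by the generator.
    The serialized config plus ``seed`` fully determine every stochastic
    output (simulation and Monte Carlo mediation intervals).
    """

    sim: Optional[SimConfig] = None
    baseline_path: Optional[str] = None
    weekly_path: Optional[str] = None
    out_dir: str = "srres_results"

    alpha: float = Field(0.05, gt=0.0, lt=1.0)
    n_primary_hypotheses: int = Field(2, ge=1)
    mc_draws: int = Field(1_000_000, ge=1000)
    min_followups: int = Field(4, ge=1)
    candidate_covariates: list[str] = Field(
        default_factory=lambda: ["education", "general_health", "diagnosis",
                                 "risk_group", "opinion_measures"])
    seed: int = 0

    @model_validator(mode="after")
    def _input_source(self) -> "PipelineConfig":
        if self.sim is None and (self.baseline_path is None or self.weekly_path is None):
            raise ValueError("either sim or both baseline_path and weekly_path are required")
        return self
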