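"""Person-level association and mediation models.

Cross-sectional (baseline SR) and prospective (mean follow-up SR)
associations of each resilience factor with stressor reactivity, as
separate multiple regressions with fully standardized coefficients, plus
Baron-Kenny mediation with a distribution-of-the-product confidence
interval for the indirect effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .prep import CovariateSet

__all__ = [
    "ModelResult",
    "MediationResult",
    "standardize_frame",
    "fit_rf_model",
    "run_h1",
    "run_h2",
    "baron_kenny",
    "distribution_of_product_ci",
]

logger = logging.getLogger(__name__)

#: Resilience factors reported in the headline association analyses,
#: in display order: positive appraisal style, pandemic-specific positive
#: appraisal, optimism, self-efficacy, stress recovery, social support,
#: change in social support, behavioral coping, neuroticism.
DEFAULT_RF_ORDER = ("PA", "PAC", "OPT", "GSE", "REC", "PSS", "CSS", "BC", "NEU")


@dataclass
class ModelResult:
    """One fitted focal association."""

    predictor: str
    outcome: str
    beta_std: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    covariates: list[str] = field(default_factory=list)
    model: str = "ols"

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class MediationResult:
    """Baron-Kenny paths with a distribution-of-the-product indirect CI.

    ``indirect`` is exactly ``a * b``; the CI comes from the distribution
    of the product of two independent normals centred at the path
    estimates.
    """

    x: str
    m: str
    y: str
    a: float
    se_a: float
    b: float
    se_b: float
    c: float
    se_c: float
    c_prime: float
    se_c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    n: int = 0
    method: str = "baron_kenny+distribution_of_product"

    @property
    def significant(self) -> bool:
        """Indirect effect decided by the CI excluding zero."""
        return not (self.ci_low <= 0.0 <= self.ci_high)

    def to_dict(self) -> dict:
        return dict(self.__dict__, significant=self.significant)


def standardize_frame(table: pd.DataFrame, variables: Sequence[str],
                      ddof: int = 1) -> pd.DataFrame:
    """z-score the listed numeric variables on the given rows.

    Categorical covariates are left untouched (they enter models as dummy
    codes).  A zero-variance variable raises, naming it.
    """
    out = table.copy()
    for var in variables:
        col = out[var].astype(float)
        sd = col.std(ddof=ddof)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"variable {var!r} has zero variance on the analysis rows")
        out[var] = (col - col.mean()) / sd
    return out


def _covariate_terms(data: pd.DataFrame, covariates: Sequence[str]) -> list[str]:
    terms = []
    for cov in covariates:
        if pd.api.types.is_numeric_dtype(data[cov]):
            terms.append(cov)
        else:
            terms.append(f"C({cov})")
    return terms


def _prepare(data: pd.DataFrame, focal: Sequence[str], outcome: str,
             covariates: Sequence[str]) -> pd.DataFrame:
    cols = list(dict.fromkeys([*focal, outcome, *covariates]))
    sub = data.dropna(subset=cols)
    numeric = [c for c in cols if pd.api.types.is_numeric_dtype(sub[c])]
    return standardize_frame(sub, numeric)


def fit_rf_model(data: pd.DataFrame, rf: str, outcome: str,
                 covariates: Optional[CovariateSet] = None) -> ModelResult:
    """Multiple regression of standardized ``outcome`` on the standardized
    focal predictor plus covariates; complete cases only."""
    cov_names = covariates.names if covariates is not None else []
    sub = _prepare(data, [rf], outcome, cov_names)
    n_params = 2 + len(cov_names)
    if len(sub) <= n_params:
        raise ValueError(f"{rf}: only {len(sub)} complete rows for ~{n_params} parameters")
    rhs = " + ".join([f"Q('{rf}')"] + _covariate_terms(sub, cov_names)) or "1"
    res = smf.ols(f"Q('{outcome}') ~ {rhs}", data=sub).fit()
    key = f"Q('{rf}')"
    ci = res.conf_int().loc[key]
    return ModelResult(predictor=rf, outcome=outcome,
                       beta_std=float(res.params[key]), se=float(res.bse[key]),
                       ci_low=float(ci[0]), ci_high=float(ci[1]),
                       p=float(res.pvalues[key]), n=int(res.nobs),
                       covariates=list(cov_names),
                       model=f"ols:{outcome}~{rf}+covariates")


def _run_battery(data: pd.DataFrame, outcome: str, covariates: Optional[CovariateSet],
                 rf_columns: dict[str, str]) -> pd.DataFrame:
    rows = []
    for rf, col in rf_columns.items():
        if col not in data.columns:
            logger.warning("RF column %r missing; %s skipped", col, rf)
            continue
        res = fit_rf_model(data, col, outcome, covariates)
        d = res.to_dict()
        d["predictor"] = rf
        rows.append(d)
    return pd.DataFrame(rows)


def run_h1(baseline_data: pd.DataFrame, covariates: Optional[CovariateSet] = None,
           rf_order: Sequence[str] = DEFAULT_RF_ORDER,
           rf_prefix: str = "style_") -> pd.DataFrame:
    """Cross-sectional battery: baseline SR regressed on each baseline RF.

    ``baseline_data`` must carry an ``sr`` column (baseline SR) and one
    ``style_<RF>`` column per factor; one separate multiple regression is
    fitted per factor and the focal standardized coefficients are
    tabulated in display order.
    """
    cols = {rf: f"{rf_prefix}{rf}" for rf in rf_order}
    return _run_battery(baseline_data, "sr", covariates, cols)


def run_h2(baseline_data: pd.DataFrame, covariates: Optional[CovariateSet] = None,
           rf_order: Sequence[str] = DEFAULT_RF_ORDER,
           rf_prefix: str = "style_") -> pd.DataFrame:
    """Prospective battery: mean follow-up SR regressed on each baseline RF
    (``mean_sr`` column, longitudinal sample)."""
    cols = {rf: f"{rf_prefix}{rf}" for rf in rf_order}
    return _run_battery(baseline_data, "mean_sr", covariates, cols)


def baron_kenny(data: pd.DataFrame, x: str, m: str, y: str,
                covariates: Optional[CovariateSet] = None,
                level: float = 0.95, mc_draws: int = 1_000_000,
                seed: int = 0) -> MediationResult:
    """Baron-Kenny mediation of x on y through m, all standardized.

    Paths: a from ``m ~ x + cov``; b and c' from ``y ~ x + m + cov``;
    c from ``y ~ x + cov``.  The same covariate set enters all three
    regressions.  The indirect effect a*b gets a seeded
    distribution-of-the-product confidence interval.
    """
    cov_names = covariates.names if covariates is not None else []
    sub = _prepare(data, [x, m], y, cov_names)
    cov_terms = _covariate_terms(sub, cov_names)

    def _fit(lhs: str, rhs_vars: list[str]):
        rhs = " + ".join([f"Q('{v}')" for v in rhs_vars] + cov_terms)
        return smf.ols(f"Q('{lhs}') ~ {rhs}", data=sub).fit()

    ra = _fit(m, [x])
    rb = _fit(y, [x, m])
    rc = _fit(y, [x])
    a, se_a = float(ra.params[f"Q('{x}')"]), float(ra.bse[f"Q('{x}')"])
    b, se_b = float(rb.params[f"Q('{m}')"]), float(rb.bse[f"Q('{m}')"])
    cp, se_cp = float(rb.params[f"Q('{x}')"]), float(rb.bse[f"Q('{x}')"])
    c, se_c = float(rc.params[f"Q('{x}')"]), float(rc.bse[f"Q('{x}')"])
    lo, hi = distribution_of_product_ci(a, se_a, b, se_b, level=level,
                                        draws=mc_draws, seed=seed)
    return MediationResult(x=x, m=m, y=y, a=a, se_a=se_a, b=b, se_b=se_b,
                           c=c, se_c=se_c, c_prime=cp, se_c_prime=se_cp,
                           indirect=a * b, ci_low=lo, ci_high=hi, level=level,
                           n=int(ra.nobs))


def distribution_of_product_ci(a: float, se_a: float, b: float, se_b: float,
                               level: float = 0.95, draws: int = 1_000_000,
                               seed: int = 0) -> tuple[float, float]:
    """Confidence interval for an indirect effect by the distribution of
    the product of two normals.

    Simulates ``Z1 * Z2`` with ``Z1 ~ N(a, se_a^2)``, ``Z2 ~ N(b,
    se_b^2)`` independent (seeded Monte Carlo with quantile
    interpolation), returning the central ``level`` interval.  This
    converges to the classical tabulated distribution-of-the-product
    interval while staying reproducible across platforms.
    """
    for name, val in (("a", a), ("se_a", se_a), ("b", b), ("se_b", se_b)):
        if not np.isfinite(val):
            raise ValueError(f"{name} must be finite")
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    prod = rng.normal(a, se_a, draws) * rng.normal(b, se_b, draws)
    alpha = 1.0 - level
    lo, hi = np.quantile(prod, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)
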