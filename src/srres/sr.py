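"""The stressor-reactivity (SR) statistic.

SR operationalizes outcome-based resilience: regress mental-health
problems P on stressor exposure E across the sample to obtain a normative
E-P line, then score each observation by its residual

    sr = P - (b0 + b1 * E).

A negative residual means fewer symptoms than expected for the
experienced exposure, i.e. higher inferred resilience.  The line is
fitted by OLS on one observation per participant (cross-sectional use)
or by the fixed effects of a linear mixed model with correlated random
intercepts and E-slopes per participant (repeated weekly data), after a
Mahalanobis outlier gate on the (E, P) distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .lmm import LMMResult, fit_lmm

__all__ = [
    "NormativeLine",
    "MAHALANOBIS_P_CUTOFF",
    "mahalanobis_outliers",
    "fit_normative_ols",
    "fit_normative_mixed",
    "test_polynomial_term",
    "compute_sr",
    "average_sr",
]

logger = logging.getLogger(__name__)

#: Upper-tail probability of the chi-square(2) outlier gate.
MAHALANOBIS_P_CUTOFF = 0.001


@dataclass
class NormativeLine:
    """Fixed-effect intercept/slope of the sample E-P line."""

    intercept: float
    slope: float
    method: str  # "ols" | "mixed_fixed_effects"
    n_obs: int
    n_outliers_removed: int = 0
    intercept_se: Optional[float] = None
    slope_se: Optional[float] = None
    structure: Optional[str] = None  # random-effect structure actually used
    converged: bool = True
    random_effect_sd: Optional[dict] = None

    def __post_init__(self):
        if not (np.isfinite(self.intercept) and np.isfinite(self.slope)):
            raise ValueError("normative line coefficients must be finite")
        if self.n_obs <= 2:
            raise ValueError("normative line needs more than 2 observations")

    def predict(self, e):
        return self.intercept + self.slope * np.asarray(e, dtype=float)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def mahalanobis_outliers(e, p, cutoff_p: float = MAHALANOBIS_P_CUTOFF):
    """Flag bivariate (E, P) outliers by squared Mahalanobis distance.

    Distances are computed from the sample mean and covariance; a pair is
    excluded when D^2 exceeds the chi-square(df=2) upper ``cutoff_p``
    quantile (13.8155 at the conventional p < .001 gate).

    Returns ``(retain_mask, d2, threshold)``.
    """
    e = np.asarray(e, dtype=float)
    p = np.asarray(p, dtype=float)
    if e.shape != p.shape or e.ndim != 1:
        raise ValueError("E and P must be 1-D arrays of equal length")
    if len(e) < 3:
        raise ValueError("need at least 3 (E, P) pairs")
    xy = np.column_stack([e, p])
    cov = np.cov(xy, rowvar=False)
    det = np.linalg.det(cov)
    if not np.isfinite(det) or det <= 1e-12 * max(cov[0, 0] * cov[1, 1], 1e-30):
        raise np.linalg.LinAlgError(
            "singular (E, P) covariance; add jitter to the data or gate manually")
    diff = xy - xy.mean(axis=0)
    d2 = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)
    threshold = stats.chi2.ppf(1.0 - cutoff_p, df=2)
    return d2 <= threshold, d2, float(threshold)


def fit_normative_ols(e, p, n_outliers_removed: int = 0) -> NormativeLine:
    """OLS fit of P ~ 1 + E on (already outlier-gated) pairs."""
    e = np.asarray(e, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.var(e) == 0:
        raise ValueError("E has zero variance; the normative line is undefined")
    res = sm.OLS(p, sm.add_constant(e)).fit()
    return NormativeLine(intercept=float(res.params[0]), slope=float(res.params[1]),
                         method="ols", n_obs=len(e),
                         n_outliers_removed=n_outliers_removed,
                         intercept_se=float(res.bse[0]), slope_se=float(res.bse[1]))


_FALLBACK_LADDER = ("correlated", "diagonal", "intercept")


def _mixed_ep_fit(data: pd.DataFrame, structure: str, reml: bool) -> LMMResult:
    X = np.column_stack([np.ones(len(data)), data["E"].to_numpy(dtype=float)])
    Z = X if structure in ("correlated", "diagonal") else X[:, :1]
    return fit_lmm(data["P"].to_numpy(dtype=float), X, Z,
                   data["participant_id"].to_numpy(),
                   fe_names=["Intercept", "E"], reml=reml, structure=structure)


def fit_normative_mixed(data: pd.DataFrame, reml: bool = True,
                        n_outliers_removed: int = 0) -> NormativeLine:
    """Mixed-model fit of the longitudinal E-P line.

    ``data`` is a long table with participant_id, E, P (all retained
    weeks, pooled).  The model is P ~ 1 + E with correlated random
    intercepts and E-slopes per participant; the returned line is the
    fixed-effect estimate, a normative summary of the sample over the
    whole observation period.  On non-convergence the random structure is
    simplified stepwise (drop the intercept-slope correlation, then the
    random slope, then fall back to OLS), with each step logged.
    """
    if data["E"].var() == 0:
        raise ValueError("E has zero variance; the normative line is undefined")
    if data.groupby("participant_id").size().max() < 2:
        # no repeated measures anywhere: random effects are unidentifiable
        logger.warning("all participants have a single observation; "
                       "fitting the line by OLS")
        line = fit_normative_ols(data["E"], data["P"], n_outliers_removed)
        line.structure = "singleton_groups_ols"
        return line
    last_exc: Optional[Exception] = None
    for structure in _FALLBACK_LADDER:
        try:
            res = _mixed_ep_fit(data, structure, reml)
        except np.linalg.LinAlgError as exc:  # degenerate profile
            last_exc = exc
            logger.warning("normative mixed fit (%s) failed: %s", structure, exc)
            continue
        if res.converged:
            if structure != "correlated":
                logger.warning("normative mixed fit fell back to %r structure", structure)
            sds = {"intercept": float(np.sqrt(res.psi[0, 0])), "residual": float(np.sqrt(res.sigma2))}
            if res.psi.shape[0] > 1:
                sds["slope"] = float(np.sqrt(res.psi[1, 1]))
            return NormativeLine(intercept=float(res.fe_params[0]),
                                 slope=float(res.fe_params[1]),
                                 method="mixed_fixed_effects",
                                 n_obs=res.n_obs,
                                 n_outliers_removed=n_outliers_removed,
                                 intercept_se=float(res.bse[0]),
                                 slope_se=float(res.bse[1]),
                                 structure=structure, converged=True,
                                 random_effect_sd=sds)
        logger.warning("normative mixed fit (%s) did not converge; simplifying", structure)
    logger.warning("all mixed structures failed (%s); falling back to OLS", last_exc)
    line = fit_normative_ols(data["E"], data["P"], n_outliers_removed)
    line.structure = "ols_fallback"
    line.converged = False
    return line


def test_polynomial_term(data: pd.DataFrame, method: str = "cross") -> dict:
    """Does a quadratic exposure term improve the E-P model?

    Cross-sectional: partial F-test for E^2 added to the OLS line.
    Longitudinal: likelihood-ratio chi-square(1) between ML-fitted mixed
    models with and without E^2 (random structure unchanged).  Both model
    pairs are fitted on identical rows.
    """
    data = data.dropna(subset=["E", "P"])
    e = data["E"].to_numpy(dtype=float)
    p = data["P"].to_numpy(dtype=float)
    if method == "cross":
        X1 = sm.add_constant(e)
        X2 = np.column_stack([X1, e**2])
        r1 = sm.OLS(p, X1).fit()
        r2 = sm.OLS(p, X2).fit()
        delta = max(0.0, r1.ssr - r2.ssr)
        df2 = float(r2.df_resid)
        tiny = 1e-12 * max(r1.ssr, 1.0)
        if delta <= tiny:  # the quadratic term adds nothing (incl. exact fits)
            f, pval = 0.0, 1.0
        elif r2.ssr <= tiny:
            f, pval = float("inf"), 0.0
        else:
            f = delta / (r2.ssr / df2)
            pval = float(stats.f.sf(f, 1, df2))
        return {"statistic": float(f), "p": float(pval), "df": (1, int(df2)),
                "test": "F"}
    if method == "long":
        X1 = np.column_stack([np.ones(len(e)), e])
        X2 = np.column_stack([X1, e**2])
        Z = X1
        groups = data["participant_id"].to_numpy()
        r1 = fit_lmm(p, X1, Z, groups, reml=False, structure="correlated")
        r2 = fit_lmm(p, X2, Z, groups, reml=False, structure="correlated")
        lr = max(0.0, 2.0 * (r2.llf - r1.llf))
        return {"statistic": float(lr), "p": float(stats.chi2.sf(lr, df=1)), "df": 1,
                "test": "LRT"}
    raise ValueError("method must be 'cross' or 'long'")


def compute_sr(line: NormativeLine, observations: pd.DataFrame,
               retain_mask=None, include_excluded: bool = False) -> pd.DataFrame:
    """Residualize each observation's P on the normative line.

    Adds an ``sr`` column (``P - (b0 + b1 E)``); rows flagged as outliers
    by ``retain_mask`` get a missing SR unless ``include_excluded`` --
    they were removed from the analysis, not re-scored.  Missing E or P
    propagate to missing sr.
    """
    out = observations.copy()
    sr = out["P"].astype(float) - line.predict(out["E"].astype(float))
    if retain_mask is not None and not include_excluded:
        sr = sr.where(np.asarray(retain_mask, dtype=bool))
    out["sr"] = sr
    return out


def average_sr(sr_table: pd.DataFrame) -> pd.Series:
    """Per-participant mean SR over retained follow-up weeks (t >= 1).

    Participants with no retained follow-up get NaN (dropped by callers).
    """
    fu = sr_table[sr_table["t"] >= 1]
    means = fu.groupby("participant_id")["sr"].mean()
    means.name = "mean_sr"
    return means
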