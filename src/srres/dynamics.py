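"""Within-person weekly dynamics of resilience factors and reactivity.

Each time-varying predictor is split into a stable between-person part
(its per-person mean over retained follow-up weeks) and a fluctuating
within-person part (the weekly deviation from that mean).  Mixed models
with a participant random intercept and a random slope on the demeaned
predictor estimate contemporaneous (same week) and lagged (one week
ahead) associations; an autoregressive follow-up re-tests any lagged
effect with the time-t measurement of the outcome added, and a 1-1-1
style mediation combines two within-person fixed-effect paths through
the distribution-of-the-product interval.

Standardization convention: the outcome and the raw time-varying
predictor are z-scored on the analysis rows *before* the within/between
decomposition, so both parts are on a common scale and the reported
coefficients are fully standardized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from patsy import dmatrix

from .lmm import LMMResult, fit_lmm
from .prep import CovariateSet
from .regression import MediationResult, distribution_of_product_ci, standardize_frame

__all__ = [
    "MixedResult",
    "person_center",
    "fit_contemporaneous",
    "fit_lagged",
    "fit_autoregressive_followup",
    "icc",
    "multilevel_mediation_contemporaneous",
]

logger = logging.getLogger(__name__)

_LADDER = ("correlated", "diagonal", "intercept")


@dataclass
class MixedResult:
    """Within- and between-person coefficients from one mixed model."""

    predictor: str
    outcome: str
    within_beta: float
    within_se: float
    within_ci: tuple[float, float]
    within_p: float
    between_beta: float
    between_se: float
    between_ci: tuple[float, float]
    between_p: float
    n_obs: int
    n_participants: int
    structure: str
    converged: bool
    random_effect_sd: dict = field(default_factory=dict)
    covariates: list[str] = field(default_factory=list)
    model: str = "mixed"
    extra_terms: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["within_ci_low"], d["within_ci_high"] = d.pop("within_ci")
        d["between_ci_low"], d["between_ci_high"] = d.pop("between_ci")
        return d


def person_center(panel: pd.DataFrame, variable: str,
                  by: str = "participant_id") -> pd.DataFrame:
    """Split a time-varying variable into person mean and weekly deviation.

    Adds ``<variable>_pm`` (mean over the rows present per person) and
    ``<variable>_dm`` (value minus that mean); the identity
    value = pm + dm holds exactly and per-person deviations sum to zero.
    """
    out = panel.copy()
    pm = out.groupby(by)[variable].transform("mean")
    out[f"{variable}_pm"] = pm
    out[f"{variable}_dm"] = out[variable] - pm
    return out


def _ladder_fit(y, X, Z, groups, fe_names, reml=True):
    last_exc = None
    for structure in _LADDER:
        Zs = Z if structure != "intercept" else Z[:, :1]
        try:
            res = fit_lmm(y, X, Zs, groups, fe_names=fe_names, reml=reml,
                          structure=structure)
        except np.linalg.LinAlgError as exc:
            last_exc = exc
            logger.warning("mixed fit (%s) failed: %s", structure, exc)
            continue
        if res.converged:
            if structure != "correlated":
                logger.warning("mixed fit fell back to %r random structure", structure)
            return res
    raise np.linalg.LinAlgError(f"no random structure converged ({last_exc})")


def _design(sub: pd.DataFrame, fixed_vars: Sequence[str],
            covariates: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    terms = list(fixed_vars)
    for cov in covariates:
        terms.append(cov if pd.api.types.is_numeric_dtype(sub[cov]) else f"C({cov})")
    mat = dmatrix(" + ".join(terms) if terms else "1", sub, return_type="dataframe")
    return mat.to_numpy(dtype=float), list(mat.columns)


def _wb_mixed(data: pd.DataFrame, outcome: str, predictor: str,
              covariates: Optional[CovariateSet], extra: Sequence[str] = (),
              random_slope: bool = True, reml: bool = True,
              model_tag: str = "mixed") -> MixedResult:
    """Core within/between mixed fit shared by all dynamic analyses."""
    cov_names = covariates.names if covariates is not None else []
    cols = list(dict.fromkeys([outcome, predictor, *extra, *cov_names,
                               "participant_id"]))
    sub = data.dropna(subset=[c for c in cols if c in data.columns]).copy()
    if sub.empty:
        raise ValueError("no complete rows for the mixed model")
    numeric = [c for c in (outcome, predictor, *extra) if c in sub.columns]
    numeric += [c for c in cov_names if pd.api.types.is_numeric_dtype(sub[c])]
    sub = standardize_frame(sub, list(dict.fromkeys(numeric)))
    sub = person_center(sub, predictor)
    dm, pm = f"{predictor}_dm", f"{predictor}_pm"
    if sub[dm].abs().max() < 1e-12:
        raise ValueError(f"{predictor}: no within-person variation; "
                         "the demeaned slope is inestimable")
    X, names = _design(sub, [dm, pm, *extra], cov_names)
    y = sub[outcome].to_numpy(dtype=float)
    groups = sub["participant_id"].to_numpy()
    Z = np.column_stack([np.ones(len(sub)), sub[dm].to_numpy(dtype=float)]) \
        if random_slope else np.ones((len(sub), 1))
    res = _ladder_fit(y, X, Z, groups, names, reml=reml)
    ci = res.conf_int()
    pvals = res.pvalues()
    i_w, i_b = names.index(dm), names.index(pm)
    sds = {"intercept": float(np.sqrt(res.psi[0, 0])),
           "residual": float(np.sqrt(res.sigma2))}
    if res.psi.shape[0] > 1:
        sds["slope"] = float(np.sqrt(res.psi[1, 1]))
    extra_terms = {}
    for name in extra:
        j = names.index(name)
        extra_terms[name] = {"beta": float(res.fe_params[j]), "se": float(res.bse[j]),
                             "p": float(pvals[j])}
    return MixedResult(
        predictor=predictor, outcome=outcome,
        within_beta=float(res.fe_params[i_w]), within_se=float(res.bse[i_w]),
        within_ci=(float(ci[i_w, 0]), float(ci[i_w, 1])), within_p=float(pvals[i_w]),
        between_beta=float(res.fe_params[i_b]), between_se=float(res.bse[i_b]),
        between_ci=(float(ci[i_b, 0]), float(ci[i_b, 1])), between_p=float(pvals[i_b]),
        n_obs=res.n_obs, n_participants=res.n_groups, structure=res.structure,
        converged=res.converged, random_effect_sd=sds, covariates=list(cov_names),
        model=model_tag, extra_terms=extra_terms)


def fit_contemporaneous(data: pd.DataFrame, rf: str, outcome: str = "sr",
                        covariates: Optional[CovariateSet] = None) -> MixedResult:
    """Same-week association between a weekly RF mode and SR.

    ``data`` holds the retained follow-up rows (one per participant-week)
    with the RF column, an ``sr`` column, and any covariates merged in.
    """
    sub = data[data["t"] >= 1]
    return _wb_mixed(sub, outcome, rf, covariates,
                     model_tag=f"contemporaneous:{outcome}~{rf}")


def _lagged_pairs(data: pd.DataFrame, predictor: str, outcome: str) -> pd.DataFrame:
    """Pairs (predictor at t, outcome at t+1) from consecutive retained
    follow-up weeks; pairs never bridge a dropped week.

    The predictor's person mean is its average over all retained
    follow-up weeks (the 'average weekly mode'), computed before pairing.
    """
    fu = data[data["t"] >= 1].sort_values(["participant_id", "t"])
    nxt = fu[["participant_id", "t", outcome]].copy()
    nxt["t"] = nxt["t"] - 1  # align outcome at t+1 onto predictor row t
    nxt = nxt.rename(columns={outcome: f"{outcome}_next"})
    merged = fu.merge(nxt, on=["participant_id", "t"], how="inner")
    return merged


def fit_lagged(data: pd.DataFrame, predictor: str, outcome: str = "sr",
               covariates: Optional[CovariateSet] = None,
               autoregressive: bool = False) -> MixedResult:
    """One-week-lagged association: predictor at week t, outcome at t+1.

    With ``autoregressive=True`` the raw week-t measurement of the outcome
    is added as a fixed-effect predictor, so the lagged coefficient
    reflects association with the *change* in the outcome beyond its
    persistence.  (Person-mean centering the lagged outcome is avoided on
    purpose: the person mean would condition on future outcome values and
    act as a collider.)
    """
    fu = data[data["t"] >= 1]
    # z-score the raw predictor and take person means over *all* retained
    # follow-up weeks (the average weekly mode), then form the lagged pairs
    fu = person_center(standardize_frame(
        fu.dropna(subset=[predictor]), [predictor]), predictor)
    merged = _lagged_pairs(fu, predictor, outcome)
    if merged.empty:
        raise ValueError("no consecutive retained week pairs available")
    out_next = f"{outcome}_next"
    extra = (outcome,) if autoregressive else ()
    # person means were computed over all retained follow-up weeks above;
    # _wb_mixed would recompute them over the paired rows only, so freeze
    # the decomposition by renaming and passing pre-centered columns.
    return _wb_mixed_precentred(merged, out_next, predictor, covariates,
                                extra=extra,
                                model_tag=("lagged_ar" if autoregressive else "lagged")
                                + f":{out_next}~{predictor}")


def _wb_mixed_precentred(data: pd.DataFrame, outcome: str, predictor: str,
                         covariates: Optional[CovariateSet],
                         extra: Sequence[str] = (),
                         model_tag: str = "mixed") -> MixedResult:
    """As :func:`_wb_mixed` but trusting existing ``_pm``/``_dm`` columns
    (person means taken over the full retained panel, not just the rows
    entering the model).  The outcome, raw predictor and numeric
    covariates are still z-scored on the analysis rows; the predictor's
    z-scoring is inherited from the pre-centering step."""
    cov_names = covariates.names if covariates is not None else []
    dm, pm = f"{predictor}_dm", f"{predictor}_pm"
    cols = [outcome, dm, pm, *extra, *cov_names, "participant_id"]
    sub = data.dropna(subset=[c for c in cols if c in data.columns]).copy()
    if sub.empty:
        raise ValueError("no complete rows for the mixed model")
    numeric = [outcome, *extra]
    numeric += [c for c in cov_names if pd.api.types.is_numeric_dtype(sub[c])]
    sub = standardize_frame(sub, list(dict.fromkeys(numeric)))
    if sub[dm].abs().max() < 1e-12:
        raise ValueError(f"{predictor}: no within-person variation")
    X, names = _design(sub, [dm, pm, *extra], cov_names)
    y = sub[outcome].to_numpy(dtype=float)
    Z = np.column_stack([np.ones(len(sub)), sub[dm].to_numpy(dtype=float)])
    res = _ladder_fit(y, X, Z, sub["participant_id"].to_numpy(), names)
    ci = res.conf_int()
    pvals = res.pvalues()
    i_w, i_b = names.index(dm), names.index(pm)
    sds = {"intercept": float(np.sqrt(res.psi[0, 0])),
           "residual": float(np.sqrt(res.sigma2))}
    if res.psi.shape[0] > 1:
        sds["slope"] = float(np.sqrt(res.psi[1, 1]))
    extra_terms = {name: {"beta": float(res.fe_params[names.index(name)]),
                          "se": float(res.bse[names.index(name)]),
                          "p": float(pvals[names.index(name)])}
                   for name in extra}
    return MixedResult(
        predictor=predictor, outcome=outcome,
        within_beta=float(res.fe_params[i_w]), within_se=float(res.bse[i_w]),
        within_ci=(float(ci[i_w, 0]), float(ci[i_w, 1])), within_p=float(pvals[i_w]),
        between_beta=float(res.fe_params[i_b]), between_se=float(res.bse[i_b]),
        between_ci=(float(ci[i_b, 0]), float(ci[i_b, 1])), between_p=float(pvals[i_b]),
        n_obs=res.n_obs, n_participants=res.n_groups, structure=res.structure,
        converged=res.converged, random_effect_sd=sds, covariates=list(cov_names),
        model=model_tag, extra_terms=extra_terms)


def fit_autoregressive_followup(data: pd.DataFrame, predictor: str,
                                outcome: str = "sr",
                                covariates: Optional[CovariateSet] = None) -> MixedResult:
    """Lagged model augmented with the outcome's week-t value, the
    follow-up analysis applied to any significant lagged association."""
    return fit_lagged(data, predictor, outcome, covariates, autoregressive=True)


def icc(panel: pd.DataFrame, variable: str,
        by: str = "participant_id") -> dict:
    """Intraclass correlation of a repeated measure.

    From a random-intercept-only model: between-person variance over
    total variance.  Degenerate variance decompositions return 0 or 1
    with a flag instead of failing.
    """
    sub = panel.dropna(subset=[variable])
    y = sub[variable].to_numpy(dtype=float)
    res = fit_lmm(y, np.ones((len(sub), 1)), np.ones((len(sub), 1)),
                  sub[by].to_numpy(), reml=True, structure="intercept")
    vb, ve = float(res.psi[0, 0]), float(res.sigma2)
    total = vb + ve
    if total <= 0:
        return {"icc": float("nan"), "var_between": vb, "var_residual": ve,
                "degenerate": True}
    return {"icc": vb / total, "var_between": vb, "var_residual": ve,
            "degenerate": bool(vb / total in (0.0, 1.0))}


def multilevel_mediation_contemporaneous(
        data: pd.DataFrame, x: str, m: str, outcome: str = "sr",
        covariates: Optional[CovariateSet] = None, level: float = 0.95,
        mc_draws: int = 1_000_000, seed: int = 0) -> MediationResult:
    """Contemporaneous within-person mediation of x on SR through m.

    Path a: mixed model of the mediator on the demeaned predictor (plus
    person means and covariates); path b: mixed model of the outcome on
    the demeaned mediator controlling the demeaned predictor.  Both paths
    are fixed slopes with participant random intercepts; the indirect
    effect a*b gets a distribution-of-the-product interval.
    """
    cov_names = covariates.names if covariates is not None else []
    sub = data[data["t"] >= 1].dropna(
        subset=[c for c in {x, m, outcome, *cov_names} if c in data.columns]).copy()
    numeric = [x, m, outcome] + [c for c in cov_names
                                 if pd.api.types.is_numeric_dtype(sub[c])]
    sub = standardize_frame(sub, list(dict.fromkeys(numeric)))
    sub = person_center(sub, x)
    sub = person_center(sub, m)
    y_arr = {v: sub[v].to_numpy(dtype=float) for v in (m, outcome)}
    groups = sub["participant_id"].to_numpy()
    Z = np.ones((len(sub), 1))

    def _fit(lhs: str, fixed: list[str]):
        X, names = _design(sub, fixed, cov_names)
        return fit_lmm(y_arr[lhs], X, Z, groups, fe_names=names,
                       reml=True, structure="intercept"), names

    ra, na = _fit(m, [f"{x}_dm", f"{x}_pm"])
    rb, nb = _fit(outcome, [f"{m}_dm", f"{x}_dm", f"{m}_pm", f"{x}_pm"])
    rc, nc = _fit(outcome, [f"{x}_dm", f"{x}_pm"])
    ia = na.index(f"{x}_dm")
    ib, icp = nb.index(f"{m}_dm"), nb.index(f"{x}_dm")
    ic = nc.index(f"{x}_dm")
    a, se_a = float(ra.fe_params[ia]), float(ra.bse[ia])
    b, se_b = float(rb.fe_params[ib]), float(rb.bse[ib])
    cp, se_cp = float(rb.fe_params[icp]), float(rb.bse[icp])
    c, se_c = float(rc.fe_params[ic]), float(rc.bse[ic])
    lo, hi = distribution_of_product_ci(a, se_a, b, se_b, level=level,
                                        draws=mc_draws, seed=seed)
    return MediationResult(x=x, m=m, y=outcome, a=a, se_a=se_a, b=b, se_b=se_b,
                           c=c, se_c=se_c, c_prime=cp, se_c_prime=se_cp,
                           indirect=a * b, ci_low=lo, ci_high=hi, level=level,
                           n=ra.n_obs,
                           method="multilevel_fixed_slopes+distribution_of_product")
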