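"""Sample retention rules and the data-driven covariate screen.

Follow-up spacing filter (gap to the previous retained assessment must be
5--9 days), longitudinal-sample membership (baseline plus at least four
retained follow-ups), the p < .2 likelihood-ratio covariate screen, and
the top-two-tertile exposure subsample used for sensitivity reanalysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .lmm import fit_lmm

__all__ = [
    "CovariateSet",
    "filter_followup_spacing",
    "filter_completion",
    "screen_covariates",
    "top_tertile_subset",
]

logger = logging.getLogger(__name__)

ALWAYS_INCLUDED = ("age", "gender", "language")
SPACING_MIN_DAYS = 5
SPACING_MAX_DAYS = 9
SCREEN_ALPHA = 0.2
MIN_FOLLOWUPS = 4


@dataclass
class CovariateSet:
    """Covariates entering downstream models.

    ``always_included`` are fixed by design; ``screened_in`` maps each
    retained data-driven covariate to its screen p-value (< .2).
    """

    always_included: tuple[str, ...] = ALWAYS_INCLUDED
    screened_in: dict[str, float] = field(default_factory=dict)
    candidates: tuple[str, ...] = ()
    sample_kind: str = "cross"

    @property
    def names(self) -> list[str]:
        return list(self.always_included) + list(self.screened_in)


def filter_followup_spacing(weekly: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop follow-ups spaced < 5 or > 9 days from the previous retained
    assessment; the baseline (t = 0) is always retained.

    "Previous sampling time point" is read as the previous *retained*
    assessment, so after a dropped week the next one is judged against the
    last week that survived.  Returns (retained_rows, drop_log); the drop
    log partitions removed rows by a single reason code each
    (gap_too_short / gap_too_long / missing_date / no_prior_baseline).
    """
    wk = weekly.sort_values(["participant_id", "t"], kind="stable").reset_index(drop=True)
    keep_pos: list[int] = []
    dropped: list[tuple] = []
    for pid, grp in wk.groupby("participant_id", sort=False):
        last_date = None
        for pos, row in zip(grp.index, grp.itertuples(index=False)):
            if row.t == 0:
                keep_pos.append(pos)
                last_date = row.date
                continue
            if pd.isna(row.date):
                dropped.append((pos, pid, row.t, "missing_date"))
                continue
            if last_date is None:
                dropped.append((pos, pid, row.t, "no_prior_baseline"))
                continue
            gap = (row.date - last_date).days
            if gap < SPACING_MIN_DAYS:
                dropped.append((pos, pid, row.t, "gap_too_short"))
            elif gap > SPACING_MAX_DAYS:
                dropped.append((pos, pid, row.t, "gap_too_long"))
            else:
                keep_pos.append(pos)
                last_date = row.date
    drop_log = pd.DataFrame(dropped, columns=["row", "participant_id", "t", "reason"])
    logger.info("spacing filter: %d rows retained, %d dropped",
                len(keep_pos), len(drop_log))
    return wk.iloc[keep_pos].reset_index(drop=True), drop_log


def filter_completion(weekly_retained: pd.DataFrame,
                      min_followups: int = MIN_FOLLOWUPS) -> pd.Index:
    """Participants eligible for longitudinal analyses: present at
    baseline and with at least ``min_followups`` retained follow-ups."""
    has_baseline = set(weekly_retained.loc[weekly_retained["t"] == 0, "participant_id"])
    fu_counts = (weekly_retained[weekly_retained["t"] >= 1]
                 .groupby("participant_id").size())
    eligible = [pid for pid, cnt in fu_counts.items()
                if cnt >= min_followups and pid in has_baseline]
    return pd.Index(sorted(eligible), name="participant_id")


def _screen_one_cross(df: pd.DataFrame, candidate: str) -> float:
    sub = df.dropna(subset=["sr", candidate])
    if sub[candidate].nunique() <= 1:
        return 1.0
    r0 = smf.ols("sr ~ 1", data=sub).fit()
    term = candidate if pd.api.types.is_numeric_dtype(sub[candidate]) else f"C({candidate})"
    r1 = smf.ols(f"sr ~ {term}", data=sub).fit()
    lr = max(0.0, 2.0 * (r1.llf - r0.llf))
    df_diff = r1.df_model - r0.df_model
    return float(stats.chi2.sf(lr, df=df_diff))


def _screen_one_long(df: pd.DataFrame, candidate: str) -> float:
    sub = df.dropna(subset=["sr", candidate])
    if sub[candidate].nunique() <= 1:
        return 1.0
    y = sub["sr"].to_numpy(dtype=float)
    groups = sub["participant_id"].to_numpy()
    Z = np.ones((len(sub), 1))
    X0 = np.ones((len(sub), 1))
    if pd.api.types.is_numeric_dtype(sub[candidate]):
        X1 = np.column_stack([X0, sub[candidate].to_numpy(dtype=float)])
    else:
        dummies = pd.get_dummies(sub[candidate], drop_first=True, dtype=float)
        X1 = np.column_stack([X0, dummies.to_numpy()])
    r0 = fit_lmm(y, X0, Z, groups, reml=False, structure="intercept")
    r1 = fit_lmm(y, X1, Z, groups, reml=False, structure="intercept")
    lr = max(0.0, 2.0 * (r1.llf - r0.llf))
    return float(stats.chi2.sf(lr, df=X1.shape[1] - X0.shape[1]))


def screen_covariates(data: pd.DataFrame, candidates, sample_kind: str = "cross",
                      alpha: float = SCREEN_ALPHA) -> CovariateSet:
    """Univariate likelihood-ratio screen of candidate covariates on SR.

    Cross-sectional: OLS of baseline SR on each candidate vs an
    intercept-only model.  Longitudinal: random-intercept mixed model on
    weekly SR (ML), candidate vs intercept-only.  Candidates with LRT
    p < ``alpha`` are retained, on top of the always-included set (age,
    gender, survey language).  Constant candidates are excluded with a
    warning (LRT statistic 0).
    """
    screened: dict[str, float] = {}
    for cand in candidates:
        if cand not in data.columns:
            logger.warning("candidate covariate %r missing from data; skipped", cand)
            continue
        if data[cand].nunique(dropna=True) <= 1:
            logger.warning("candidate covariate %r is constant; excluded", cand)
            continue
        p = (_screen_one_cross if sample_kind == "cross" else _screen_one_long)(data, cand)
        if p < alpha:
            screened[cand] = p
    return CovariateSet(screened_in=screened, candidates=tuple(candidates),
                        sample_kind=sample_kind)


def top_tertile_subset(mean_e: pd.Series) -> pd.Index:
    """Participants in the top two tertiles of mean stressor exposure.

    The lower-tertile boundary is inclusive and ties are kept, so the
    subsample is never smaller than two thirds of the input.
    """
    mean_e = mean_e.dropna()
    if len(mean_e) < 3:
        raise ValueError("need at least 3 participants for a tertile split")
    boundary = np.quantile(mean_e.to_numpy(dtype=float), 1.0 / 3.0)
    return mean_e.index[mean_e >= boundary]
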