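"""Raw-item scoring and panel loading/validation.

Turns item-level survey responses into the three analysis variables:
stressor exposure E (sum of 0--5 burden severities over the stressor
checklist), mental-health problems P (GHQ-12 total on 0-1-2-3 Likert
scoring, range 0--36) and resilience-factor scale scores (definition
driven, with reverse coding and a >=80% answered rule).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScaleDefinition",
    "ValidationError",
    "PanelValidationError",
    "score_stressor_exposure",
    "score_ghq",
    "score_scale",
    "score_weekly_frame",
    "load_panel",
]

logger = logging.getLogger(__name__)

GHQ_N_ITEMS = 12
GHQ_MAX = 3
SEVERITY_MAX = 5
MIN_ANSWERED_FRACTION = 0.8


class ValidationError(ValueError):
    """An item response violates its declared range or count."""


class PanelValidationError(ValueError):
    """Structural problems in a loaded panel; carries the offending rows."""

    def __init__(self, message: str, rows: pd.DataFrame | None = None):
        super().__init__(message)
        self.rows = rows


@dataclass(frozen=True)
class ScaleDefinition:
    """Scoring rule for one self-report scale."""

    name: str
    items: tuple[str, ...]
    response_min: float
    response_max: float
    reverse_items: tuple[str, ...] = ()
    rule: str = "sum"  # "sum" | "mean"

    def __post_init__(self):
        if len(set(self.items)) != len(self.items):
            raise ValueError(f"{self.name}: duplicate item ids")
        unknown = set(self.reverse_items) - set(self.items)
        if unknown:
            raise ValueError(f"{self.name}: reverse items {sorted(unknown)} not in items")
        if self.rule not in ("sum", "mean"):
            raise ValueError(f"{self.name}: rule must be 'sum' or 'mean'")


def _as_float_array(values: Iterable) -> np.ndarray:
    return np.asarray(pd.to_numeric(pd.Series(list(values)), errors="coerce"), dtype=float)


def score_stressor_exposure(severities: Iterable) -> int:
    """Sum of stressor severity ratings; each must be an integer in {0..5}."""
    arr = _as_float_array(severities)
    if np.isnan(arr).any():
        raise ValidationError("missing or non-numeric stressor severity")
    if np.any((arr < 0) | (arr > SEVERITY_MAX)) or np.any(arr != np.rint(arr)):
        raise ValidationError("stressor severities must be integers in 0..5")
    return int(arr.sum())


def score_ghq(items: Iterable) -> int:
    """GHQ-12 total sum score on 0-1-2-3 Likert coding (range 0..36)."""
    arr = _as_float_array(items)
    if len(arr) != GHQ_N_ITEMS:
        raise ValidationError(f"GHQ-12 needs exactly {GHQ_N_ITEMS} items, got {len(arr)}")
    if np.isnan(arr).any():
        raise ValidationError("missing GHQ item response")
    if np.any((arr < 0) | (arr > GHQ_MAX)) or np.any(arr != np.rint(arr)):
        raise ValidationError("GHQ items must be integers in 0..3")
    return int(arr.sum())


def score_scale(responses: Mapping[str, float], definition: ScaleDefinition) -> float:
    """Score one scale administration.

    Reverse-coded items are mapped to ``min + max - x`` first.  When at
    least 80% of items are answered, the missing ones are implicitly
    mean-imputed from the respondent's own answered items (a mean score is
    the mean of answered items; a sum score scales that mean to the full
    item count).  Below 80% the score is missing (NaN), never imputed from
    other respondents.
    """
    vals = np.array([float(responses.get(item, np.nan)) for item in definition.items])
    answered = ~np.isnan(vals)
    in_range = vals[answered]
    if np.any((in_range < definition.response_min) | (in_range > definition.response_max)):
        raise ValidationError(f"{definition.name}: response outside "
                              f"[{definition.response_min}, {definition.response_max}]")
    rev = np.isin(definition.items, definition.reverse_items)
    vals = np.where(rev, definition.response_min + definition.response_max - vals, vals)
    if answered.mean() < MIN_ANSWERED_FRACTION:
        return float("nan")
    mean = float(np.nanmean(vals))
    return mean * len(definition.items) if definition.rule == "sum" else mean


def _item_columns(frame: pd.DataFrame, prefix: str) -> list[str]:
    pat = re.compile(rf"^{prefix}\d+$")
    return sorted((c for c in frame.columns if pat.match(c)),
                  key=lambda c: int(c[len(prefix):]))


def score_weekly_frame(weekly: pd.DataFrame) -> pd.DataFrame:
    """Attach/refresh E and P columns on a weekly table.

    When stressor item columns (``s01..``) or GHQ item columns
    (``ghq01..``) are present, the totals are recomputed from them (and
    override any existing E/P columns); otherwise pre-scored E/P columns
    are required.  Rows with out-of-range items raise.
    """
    out = weekly.copy()
    sev_cols = _item_columns(out, "s")
    ghq_cols = _item_columns(out, "ghq")
    if sev_cols:
        sev = out[sev_cols].to_numpy(dtype=float)
        if np.isnan(sev).any() or ((sev < 0) | (sev > SEVERITY_MAX)).any() \
                or (sev != np.rint(sev)).any():
            raise ValidationError("stressor severities must be integers in 0..5")
        out["E"] = sev.sum(axis=1).astype(np.int64)
    elif "E" not in out.columns:
        raise ValidationError("weekly table has neither stressor items nor an E column")
    if ghq_cols:
        if len(ghq_cols) != GHQ_N_ITEMS:
            raise ValidationError(f"expected {GHQ_N_ITEMS} GHQ item columns, "
                                  f"found {len(ghq_cols)}")
        ghq = out[ghq_cols].to_numpy(dtype=float)
        if np.isnan(ghq).any() or ((ghq < 0) | (ghq > GHQ_MAX)).any() \
                or (ghq != np.rint(ghq)).any():
            raise ValidationError("GHQ items must be integers in 0..3")
        out["P"] = ghq.sum(axis=1).astype(np.int64)
    elif "P" not in out.columns:
        raise ValidationError("weekly table has neither GHQ items nor a P column")
    return out


def load_panel(baseline_path, weekly_path) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Load and validate the baseline + weekly CSV pair.

    Returns typed tables plus a validation report (row counts, warnings).
    Duplicate (participant_id, t) pairs or unparseable dates raise
    :class:`PanelValidationError` naming the offending rows.
    """
    baseline = pd.read_csv(baseline_path)
    weekly = pd.read_csv(weekly_path)
    report: dict = {"warnings": [], "n_baseline": len(baseline), "n_weekly": len(weekly)}

    for col in ("participant_id",):
        if col not in baseline.columns:
            raise PanelValidationError(f"baseline table lacks column {col!r}")
    dup_b = baseline[baseline.duplicated("participant_id", keep=False)]
    if len(dup_b):
        raise PanelValidationError(
            f"duplicate participant_id in baseline: {sorted(dup_b.participant_id.unique())}",
            rows=dup_b)

    if len(weekly) == 0:
        report["warnings"].append("weekly table is empty")
        logger.warning("weekly table %s is empty", weekly_path)
        return baseline, weekly, report

    missing = {"participant_id", "t", "date"} - set(weekly.columns)
    if missing:
        raise PanelValidationError(f"weekly table lacks columns {sorted(missing)}")
    dup = weekly[weekly.duplicated(["participant_id", "t"], keep=False)]
    if len(dup):
        pairs = sorted(
            (tuple(int(v) if isinstance(v, (int, np.integer)) else v for v in row)
             for row in dup[["participant_id", "t"]].drop_duplicates().values))
        raise PanelValidationError(f"duplicate (participant_id, t) rows: {pairs}", rows=dup)
    dates = pd.to_datetime(weekly["date"], errors="coerce")
    bad = weekly[dates.isna() & weekly["date"].notna()]
    if len(bad):
        raise PanelValidationError(
            f"unparseable dates in weekly rows {list(bad.index)}", rows=bad)
    weekly = weekly.assign(date=dates)
    weekly = score_weekly_frame(weekly)
    unknown_ids = set(weekly.participant_id) - set(baseline.participant_id)
    if unknown_ids:
        report["warnings"].append(
            f"{len(unknown_ids)} weekly participants missing from baseline")
    return baseline, weekly, report
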