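"""Pre-modelling exploratory analyses.

Change-from-baseline summaries, pooled subject-level linear regressions
with relative standard errors, and comparison of the mean-glucose vs
HbA1c relationship against published regression lines from the
literature (glucose in mg/dL as a linear function of HbA1c %).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .table import ObservationTable

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionResult", "PublishedLine", "published_lines",
    "percent_change_from_baseline", "paired_pct_changes",
    "subject_level_regression", "compare_to_published_lines",
]


@dataclass(frozen=True)
class RegressionResult:
    """OLS intercept/slope with SEs and relative standard errors (%)."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    n: int

    @property
    def rse_intercept_percent(self) -> float:
        return 100.0 * self.se_intercept / abs(self.intercept)

    @property
    def rse_slope_percent(self) -> float:
        return 100.0 * self.se_slope / abs(self.slope)


@dataclass(frozen=True)
class PublishedLine:
    """Published mean glucose (mg/dL) = intercept + slope * HbA1c (%)."""

    source: str
    intercept: float
    slope: float

    def predict(self, hba1c):
        return self.intercept + self.slope * np.asarray(hba1c, dtype=float)


def published_lines() -> tuple[PublishedLine, ...]:
    """The catalogue of literature glucose-HbA1c regression lines."""
    with resources.files("dapaer.data").joinpath("published_lines.csv").open() as f:
        df = pd.read_csv(f)
    return tuple(PublishedLine(r.source, float(r.intercept), float(r.slope))
                 for r in df.itertuples())


def percent_change_from_baseline(table: ObservationTable) -> pd.DataFrame:
    """Per subject/visit/observation-type percent change from the t=0 visit.

    Uses the observed t=0 value as the reference; rows of subjects
    without a baseline observation of that type are dropped with a
    logged count.  Baseline rows map to 0.
    """
    df = table.df
    out_frames = []
    dropped = 0
    for obs_type, sub in df.groupby("obs_type"):
        base = sub[sub["time_wk"] == 0].groupby("subject_id")["value"].first()
        ref = base.reindex(sub["subject_id"]).to_numpy()
        ok = np.isfinite(ref)
        dropped += int((~ok).sum())
        sub = sub[ok].copy()
        sub["pct_change"] = 100.0 * (sub["value"].to_numpy() - ref[ok]) / ref[ok]
        sub.loc[sub["time_wk"] == 0, "pct_change"] = 0.0
        out_frames.append(sub[["subject_id", "arm", "dose_mg", "time_wk",
                               "obs_type", "pct_change"]])
    if dropped:
        logger.warning("percent_change_from_baseline: dropped %d rows lacking "
                       "a baseline observation", dropped)
    if not out_frames:
        return pd.DataFrame(columns=["subject_id", "arm", "dose_mg", "time_wk",
                                     "obs_type", "pct_change"])
    return pd.concat(out_frames, ignore_index=True)


def paired_pct_changes(pct: pd.DataFrame, x_type: str, y_type: str,
                       arms: Sequence[str] | None = None) -> pd.DataFrame:
    """Pair percent changes of two observation types on subject and visit.

    Input is the output of :func:`percent_change_from_baseline`; only
    post-baseline visits where both types were observed are kept.
    Returns columns subject_id, arm, time_wk, x, y.
    """
    df = pct[pct["time_wk"] > 0]
    if arms is not None:
        df = df[df["arm"].isin(arms)]
    xs = df[df["obs_type"] == x_type]
    ys = df[df["obs_type"] == y_type]
    merged = xs.merge(ys, on=["subject_id", "arm", "time_wk"],
                      suffixes=("_x", "_y"))
    return merged.rename(columns={"pct_change_x": "x", "pct_change_y": "y"})[
        ["subject_id", "arm", "time_wk", "x", "y"]]


def subject_level_regression(x, y) -> RegressionResult:
    """OLS of pooled subject-level points (one point per subject-visit)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired finite observations")
    if np.std(x) == 0:
        raise ValueError("degenerate regressor: zero variance in x")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        intercept=float(res.params[0]), slope=float(res.params[1]),
        se_intercept=float(res.bse[0]), se_slope=float(res.bse[1]),
        n=int(x.size))


@dataclass(frozen=True)
class LineComparison:
    table: pd.DataFrame                    # per-line deviation summaries
    residuals: dict[str, np.ndarray]       # per-line observed - predicted
    ols: RegressionResult                  # OLS of the input pairs


def compare_to_published_lines(mean_glucose, hba1c) -> LineComparison:
    """Deviations of observed glucose from each published line.

    For every catalogued line, residuals are observed glucose minus the
    line's prediction at the observed HbA1c; an OLS of the input pairs
    (glucose ~ HbA1c) is fitted alongside.
    """
    glu = np.asarray(mean_glucose, dtype=float)
    hba1c = np.asarray(hba1c, dtype=float)
    if glu.shape != hba1c.shape:
        raise ValueError("series must be paired")
    ols = subject_level_regression(hba1c, glu)
    rows, residuals = [], {}
    for line in published_lines():
        resid = glu - line.predict(hba1c)
        residuals[line.source] = resid
        rows.append({"source": line.source, "intercept": line.intercept,
                     "slope": line.slope,
                     "mean_deviation": float(resid.mean()),
                     "rmse": float(np.sqrt(np.mean(resid ** 2)))})
    return LineComparison(table=pd.DataFrame(rows), residuals=residuals, ols=ols)
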