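"""Long-format observation table: the interchange format of the pipeline.

One row per subject-visit-observation.  Columns:

subject_id  str/int   unique subject label
arm         str       randomized arm label (e.g. "placebo", "10mg")
dose_mg     float     nominal daily dose, 0 for placebo
time_wk     float     weeks since treatment start (phase-2 days as days/7)
obs_type    str       one of OBS_TYPES
value       float     observed (noisy) value
value_pred  float     noise-free individual prediction (optional twin)
auc         float     steady-state 24-h dapagliflozin AUC, ng/mL*h
ins0, glu0, hba1c0, hgb0   subject baseline covariates

The t=0 visit is the pre-dose baseline: noise-free values equal the
baseline covariates there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OBS_TYPES = ("basal_insulin", "bolus_insulin", "cgm_glucose", "hba1c", "hemoglobin")

REQUIRED_COLUMNS = (
    "subject_id", "arm", "dose_mg", "time_wk", "obs_type", "value",
    "auc", "ins0", "glu0", "hba1c0", "hgb0",
)
OPTIONAL_COLUMNS = ("value_pred",)

_BASELINE_COL = {
    "basal_insulin": "ins0",
    "cgm_glucose": "glu0",
    "hba1c": "hba1c0",
    "hemoglobin": "hgb0",
}


@dataclass
class ObservationTable:
    """Validated wrapper around the long-format DataFrame."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"observation table missing required columns: {missing}")
        bad_types = set(self.df["obs_type"]) - set(OBS_TYPES)
        if bad_types:
            raise ValueError(f"unknown obs_type values: {sorted(bad_types)}")
        if len(self.df) and not (self.df["value"] > 0).all():
            raise ValueError("observation values must be positive")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_subjects(self) -> int:
        return self.df["subject_id"].nunique()

    def subset(self, obs_type: str) -> pd.DataFrame:
        if obs_type not in OBS_TYPES:
            raise ValueError(f"unknown obs_type {obs_type!r}")
        return self.df[self.df["obs_type"] == obs_type]

    def baseline_value(self, obs_type: str) -> pd.Series:
        """Observed t=0 value per subject for one observation type."""
        sub = self.subset(obs_type)
        base = sub[sub["time_wk"] == 0].set_index("subject_id")["value"]
        return base

    def subject_covariates(self) -> pd.DataFrame:
        """One row per subject with arm, auc and baseline covariates."""
        cols = ["arm", "dose_mg", "auc", "ins0", "glu0", "hba1c0", "hgb0"]
        return self.df.groupby("subject_id", sort=True)[cols].first()

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ObservationTable":
        return read_observation_table(path)


def read_observation_table(path) -> ObservationTable:
    """Read and validate a long-format observation CSV.

    Missing required columns raise; rows with unparseable numerics or
    nonpositive values are dropped with a logged count.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    n0 = len(df)
    if n0 == 0:
        logger.warning("%s: empty observation table (header only)", path)
        return ObservationTable(df)
    num_cols = ["dose_mg", "time_wk", "value", "auc", "ins0", "glu0", "hba1c0", "hgb0"]
    for c in num_cols + [c for c in OPTIONAL_COLUMNS if c in df.columns]:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    keep = df[num_cols].notna().all(axis=1) & (df["value"] > 0)
    keep &= df["obs_type"].isin(OBS_TYPES)
    dropped = int(n0 - keep.sum())
    if dropped:
        logger.warning("%s: dropped %d of %d rows (unparseable, nonpositive or unknown obs_type)",
                       path, dropped, n0)
    df = df[keep].reset_index(drop=True)
    logger.info("%s: read %d observations from %d subjects", path, len(df),
                df["subject_id"].nunique())
    return ObservationTable(df)


def observed_ratio(table: ObservationTable, obs_type: str) -> pd.DataFrame:
    """Observed value relative to the subject's baseline covariate.

    Uses the true baseline columns (ins0/glu0/hba1c0/hgb0) as the
    denominator; returns columns subject_id, time_wk, ratio.
    """
    col = _BASELINE_COL.get(obs_type)
    if col is None:
        raise ValueError(f"no baseline covariate for obs_type {obs_type!r}")
    sub = table.subset(obs_type)
    out = sub[["subject_id", "time_wk"]].copy()
    out["ratio"] = np.asarray(sub["value"]) / np.asarray(sub[col])
    return out
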