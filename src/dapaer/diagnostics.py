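"""Fit diagnostics: observed-vs-predicted, residuals, predictive checks."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimation import SequentialResults
from .model import StructuralParameters
from .simulate import IMAX_CLIP, VALUE_FLOOR
from .table import ObservationTable

__all__ = ["goodness_of_fit", "visual_predictive_check", "simulate_from_fit"]

_MODEL_TYPES = ("basal_insulin", "cgm_glucose", "hba1c")


def _row_predictions(df: pd.DataFrame, p: StructuralParameters,
                     eta1: np.ndarray, eta2: np.ndarray,
                     eta3: np.ndarray) -> np.ndarray:
    """Noise-free individual predictions for model observation rows.

    ``eta*`` are per-row random-effect values (already expanded from
    subjects to rows).  t=0 rows are pre-dose baselines.
    """
    t = df["time_wk"].to_numpy(dtype=float)
    auc = df["auc"].to_numpy(dtype=float)
    on = t > 0
    imax_i = np.minimum(p.imax_ins * np.exp(eta1), IMAX_CLIP)
    r = np.clip(1.0 - imax_i * auc / (p.iauc50_ins + auc), 0.05, None)
    drift = np.maximum(1.0 + (p.keff + eta2) * t, 0.01)
    gratio = drift * r ** (-p.k1) * (1.0 - p.imax_glu * auc / (p.iauc50_glu + auc))
    k2_i = p.k2 * np.exp(eta3)
    hfactor = np.maximum(1.0 + k2_i * (gratio - 1.0), 0.01)
    direct = 1.0 - p.imax_hba1c * auc / (p.iauc50_hba1c + auc)

    pred = np.empty(len(df))
    obs_type = df["obs_type"].to_numpy()
    for typ, col, on_val in (
            ("basal_insulin", "ins0", lambda m: df["ins0"].to_numpy()[m] * r[m]),
            ("cgm_glucose", "glu0", lambda m: df["glu0"].to_numpy()[m] * gratio[m]),
            ("hba1c", "hba1c0", lambda m: df["hba1c0"].to_numpy()[m] * hfactor[m] * direct[m])):
        m = obs_type == typ
        pred[m] = df[col].to_numpy()[m]
        m_on = m & on
        pred[m_on] = on_val(m_on)
    return np.maximum(pred, VALUE_FLOOR)


def _expand_etas(df: pd.DataFrame, fit: SequentialResults):
    sids = df["subject_id"].to_numpy()
    out = []
    for step in (1, 2, 3):
        s = fit.steps[step]
        series = pd.Series(s.eta, index=s.subject_ids)
        out.append(series.reindex(sids).fillna(0.0).to_numpy())
    return out


def goodness_of_fit(data: ObservationTable, fit: SequentialResults) -> dict:
    """Observed-vs-predicted pairs and binned residual summaries.

    Returns ``{"pairs": ..., "binned": ...}``.  ``pairs`` has one row
    per model observation with population prediction (all etas zero),
    individual prediction (empirical-Bayes etas) and the normalized
    residual (y - ipred)/sd(ipred) under the step's residual model;
    ``binned`` groups the normalized residuals by observation type and
    visit with a 95% CI of the bin mean.
    """
    df = data.df[data.df["obs_type"].isin(_MODEL_TYPES)].reset_index(drop=True)
    p = fit.structural
    zeros = np.zeros(len(df))
    ppred = _row_predictions(df, p, zeros, zeros, zeros)
    e1, e2, e3 = _expand_etas(df, fit)
    ipred = _row_predictions(df, p, e1, e2, e3)
    y = df["value"].to_numpy(dtype=float)
    sd = np.where(df["obs_type"] == "hba1c", p.a_hba1c,
                  np.where(df["obs_type"] == "basal_insulin",
                           p.b_ins * ipred, p.b_glu * ipred))
    pairs = df[["subject_id", "arm", "time_wk", "obs_type", "auc", "value"]].copy()
    pairs["pred_pop"] = ppred
    pairs["pred_ind"] = ipred
    pairs["resid_norm"] = (y - ipred) / sd

    def _bin(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        m = g["resid_norm"].mean()
        sem = g["resid_norm"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        return pd.Series({"n": n, "mean_resid": m,
                          "lo95": m - 1.96 * sem, "hi95": m + 1.96 * sem})

    binned = (pairs.groupby(["obs_type", "time_wk"])[["resid_norm"]]
              .apply(_bin).reset_index())
    return {"pairs": pairs, "binned": binned}


def simulate_from_fit(data: ObservationTable, fit: SequentialResults,
                      rng: np.random.Generator) -> np.ndarray:
    """One parametric simulation of the model observations at the
    observed design (same subjects, times, exposures, baselines)."""
    df = data.df[data.df["obs_type"].isin(_MODEL_TYPES)].reset_index(drop=True)
    p = fit.structural
    re = fit.random_effects
    sids = np.unique(df["subject_id"].to_numpy())
    draws = {}
    for name in ("imax_ins", "keff", "k2"):
        draws[name] = pd.Series(
            rng.normal(0.0, re.omega(name), size=sids.size), index=sids)
    sid_col = df["subject_id"].to_numpy()
    e1 = draws["imax_ins"].reindex(sid_col).to_numpy()
    e2 = draws["keff"].reindex(sid_col).to_numpy()
    e3 = draws["k2"].reindex(sid_col).to_numpy()
    pred = _row_predictions(df, p, e1, e2, e3)
    eps = rng.normal(size=pred.size)
    obs_type = df["obs_type"].to_numpy()
    y = np.where(obs_type == "hba1c", pred + p.a_hba1c * eps,
                 np.where(obs_type == "basal_insulin",
                          pred * (1 + p.b_ins * eps), pred * (1 + p.b_glu * eps)))
    return np.maximum(y, VALUE_FLOOR)


def visual_predictive_check(data: ObservationTable, fit: SequentialResults,
                            n_sim: int = 200, seed: int = 0,
                            percentiles=(5.0, 50.0, 95.0)) -> pd.DataFrame:
    """Simulation-based 95% bands for observed percentiles per visit.

    For each observation type and visit time, computes the observed
    5th/50th/95th percentiles and the 2.5-97.5% band of the same
    percentile across ``n_sim`` simulations from the fitted model.
    """
    if n_sim < 2:
        raise ValueError("n_sim must be >= 2")
    df = data.df[data.df["obs_type"].isin(_MODEL_TYPES)].reset_index(drop=True)
    rng = np.random.default_rng(seed)
    keys = df[["obs_type", "time_wk"]]
    groups = df.groupby(["obs_type", "time_wk"]).indices

    sims = np.empty((n_sim, len(df)))
    for s in range(n_sim):
        sims[s] = simulate_from_fit(data, fit, rng)

    rows = []
    y = df["value"].to_numpy(dtype=float)
    for (obs_type, t), idx in groups.items():
        obs_p = np.percentile(y[idx], percentiles)
        sim_p = np.percentile(sims[:, idx], percentiles, axis=1)  # (3, n_sim)
        lo = np.percentile(sim_p, 2.5, axis=1)
        hi = np.percentile(sim_p, 97.5, axis=1)
        med = np.percentile(sim_p, 50.0, axis=1)
        for j, q in enumerate(percentiles):
            rows.append({"obs_type": obs_type, "time_wk": t, "percentile": q,
                         "observed": obs_p[j], "sim_lo95": lo[j],
                         "sim_hi95": hi[j], "sim_median": med[j],
                         "in_band": bool(lo[j] <= obs_p[j] <= hi[j])})
    return pd.DataFrame(rows).sort_values(
        ["obs_type", "time_wk", "percentile"]).reset_index(drop=True)
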