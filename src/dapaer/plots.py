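"""Matplotlib views of the main outputs (numeric results live elsewhere)."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends first
import matplotlib.pyplot as plt

__all__ = ["plot_dose_response", "plot_titration_scan", "plot_gof", "plot_vpc"]


def plot_dose_response(dose_response: pd.DataFrame, ax=None):
    """Stacked-component bar chart of week-24 HbA1c change per arm."""
    ax = ax or plt.figure(figsize=(6, 4)).add_subplot()
    arms = dose_response["arm"].unique()
    x = np.arange(len(arms))
    for offset, comp, color in ((-0.2, "glucose_only", "firebrick"),
                                (0.2, "total", "seagreen")):
        sub = dose_response[dose_response["component"] == comp].set_index("arm")
        sub = sub.reindex(arms)
        ax.bar(x + offset, sub["mean"], width=0.35, color=color, label=comp)
        ax.errorbar(x + offset, sub["mean"],
                    yerr=[sub["mean"] - sub["lo95"], sub["hi95"] - sub["mean"]],
                    fmt="none", ecolor="black", capsize=3)
    ax.set_xticks(x, arms)
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_ylabel("change in HbA1c at week 24 (%-units)")
    ax.legend()
    return ax


def plot_titration_scan(scan: pd.DataFrame, ax=None):
    ax = ax or plt.figure(figsize=(6, 4)).add_subplot()
    for arm, sub in scan.groupby("arm"):
        sub = sub.sort_values("insulin_reduction")
        ax.plot(100 * sub["insulin_reduction"], sub["mean"], marker="o", label=arm)
        ax.fill_between(100 * sub["insulin_reduction"], sub["lo95"], sub["hi95"],
                        alpha=0.25)
    ax.set_xlabel("fixed basal insulin dose reduction (%)")
    ax.set_ylabel("change in HbA1c at week 24 (%-units)")
    ax.legend()
    return ax


def plot_gof(pairs: pd.DataFrame, obs_type: str, ax=None):
    """Observed vs individual-predicted scatter for one observation type."""
    ax = ax or plt.figure(figsize=(4.5, 4.5)).add_subplot()
    sub = pairs[pairs["obs_type"] == obs_type]
    ax.scatter(sub["pred_ind"], sub["value"], s=8, alpha=0.4)
    lims = [min(sub["pred_ind"].min(), sub["value"].min()),
            max(sub["pred_ind"].max(), sub["value"].max())]
    ax.plot(lims, lims, color="black", lw=0.8)
    ax.set_xlabel("individual prediction")
    ax.set_ylabel("observed")
    ax.set_title(obs_type)
    return ax


def plot_vpc(vpc: pd.DataFrame, obs_type: str, ax=None):
    ax = ax or plt.figure(figsize=(6, 4)).add_subplot()
    sub = vpc[vpc["obs_type"] == obs_type]
    for q, sty in ((5.0, ":"), (50.0, "-"), (95.0, ":")):
        s = sub[sub["percentile"] == q].sort_values("time_wk")
        ax.plot(s["time_wk"], s["observed"], sty, color="black",
                label=f"obs p{q:g}")
        ax.fill_between(s["time_wk"], s["sim_lo95"], s["sim_hi95"], alpha=0.25)
    ax.set_xlabel("weeks")
    ax.set_ylabel(obs_type)
    ax.legend(fontsize=7)
    return ax
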