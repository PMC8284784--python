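"""Optional matplotlib figures for the main outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # file output only; no interactive backend assumed
import matplotlib.pyplot as plt
import pandas as pd

BEHAVIOR_COLORS = {"p_water": "tab:blue", "p_flight": "black", "p_forage": "tab:red"}


def plot_dispersal_series(series: pd.DataFrame, ax=None):
    """Daily dispersal difference with its bootstrap CI ribbon.

    Zero marks spatial mixing of the colonies; positive values segregation.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    dates = pd.to_datetime(series["date"])
    ax.plot(dates, series["difference_km"], color="tab:blue", lw=1.2)
    ax.fill_between(dates, series["ci_low"], series["ci_high"], alpha=0.25, color="tab:blue")
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("date")
    ax.set_ylabel("between − within colony distance (km)")
    return ax


def plot_activity_by_phase(summary: pd.DataFrame, ax=None):
    """Grouped bars of behavior proportions per solar day-phase."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    phases = ["night", "sunrise_window", "day", "sunset_window"]
    sub = summary.set_index("phase").reindex([p for p in phases if p in set(summary["phase"])])
    x = range(len(sub))
    width = 0.27
    for k, (col, color) in enumerate(BEHAVIOR_COLORS.items()):
        ax.bar([i + (k - 1) * width for i in x], sub[col], width=width, color=color,
               label=col.replace("p_", ""))
    ax.set_xticks(list(x), sub.index)
    ax.set_ylabel("proportion of blocks")
    ax.legend()
    return ax
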