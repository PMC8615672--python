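"""Actograms, 24-h activity profiles, and rhythm-cognition scatter plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io import DayMatrix

__all__ = ["plot_actogram", "plot_average_profile", "plot_is_scatter",
           "save_report_figures"]


def plot_actogram(dm: DayMatrix, acrophases=None, double_plot: bool = True, ax=None):
    """Double-plotted actogram: one row per day, optional acrophase dots."""
    n_days, b = dm.n_days, dm.bins_per_day
    width = 2 * b if double_plot else b
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.6 * n_days + 1))
    vmax = np.percentile(dm.values, 98) or 1.0
    for d in range(n_days):
        row = dm.values[d]
        if double_plot:
            nxt = dm.values[d + 1] if d + 1 < n_days else np.zeros(b)
            row = np.concatenate([row, nxt])
        y0 = n_days - d
        ax.bar(np.arange(width) * 24.0 / b, np.clip(row / vmax, 0, 1) * 0.8,
               bottom=y0, width=24.0 / b, color="black", align="edge")
        if acrophases is not None and np.isfinite(acrophases[d]):
            ax.plot(acrophases[d], y0 + 0.4, "o", color="red", ms=5)
    ax.set_xlim(0, 48 if double_plot else 24)
    ax.set_xlabel("clock time (h)")
    ax.set_ylabel("day")
    ax.set_yticks([])
    return ax


def plot_average_profile(dm: DayMatrix, ax=None):
    """Mean 24-h activity profile with across-day spread."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    t = dm.bin_clock_hours()
    order = np.argsort(t)
    mean = dm.values.mean(axis=0)[order]
    sd = dm.values.std(axis=0)[order]
    ax.plot(t[order], mean, color="tab:blue")
    ax.fill_between(t[order], mean - sd, mean + sd, alpha=0.25, color="tab:blue")
    ax.set_xlabel("clock time (h)")
    ax.set_ylabel("activity (counts/epoch)")
    ax.set_xlim(0, 24)
    return ax


def plot_is_scatter(measures, outcome: str, ax=None):
    """Cognitive outcome against interdaily stability with an OLS fit line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    sub = measures.dropna(subset=["IS", outcome])
    x, y = sub["IS"].to_numpy(), sub[outcome].to_numpy()
    ax.scatter(x, y, s=20, alpha=0.7)
    if x.size >= 2:
        b, a = np.polyfit(x, y, 1)
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, a + b * xs, color="tab:red")
    ax.set_xlabel("interdaily stability")
    ax.set_ylabel(outcome)
    return ax


def save_report_figures(result, out_dir) -> None:
    out = Path(out_dir)
    for outcome in ("reaction_time", "verbal_recall", "scene_recall"):
        if outcome in result.measures.columns:
            ax = plot_is_scatter(result.measures, outcome)
            ax.figure.savefig(out / f"scatter_IS_{outcome}.png", dpi=110,
                              bbox_inches="tight")
            plt.close(ax.figure)
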