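"""Figures: the dual-dose differential-score scatter and 4PL curve plots."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .doseresponse import DoseResponseFit, four_pl

__all__ = ["plot_screen", "plot_dose_response"]


def plot_screen(
    scores: pd.DataFrame,
    highlight: Sequence[str] | None = None,
    highlight_label: str = "highlighted",
    ax: plt.Axes | None = None,
) -> plt.Figure:
    """Scatter of d at 100 nM (X) vs d at 1 uM (Y) with quadrant gridlines.

    Axes are symmetric about 0 so the four quadrants read directly:
    upper-right = selective against the sensitive E41K line, lower-left =
    collateral sensitivity against the resistant line. ``highlight`` marks a
    compound subset (e.g. one pharmacological class) as large colored dots
    over the grey base cloud.
    """
    if scores.empty:
        raise ValueError("scores table is empty")
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 5))
    else:
        fig = ax.figure
    x = scores["d_100"].to_numpy(dtype=float)
    y = scores["d_1000"].to_numpy(dtype=float)
    ax.scatter(x, y, s=12, c="0.6", alpha=0.7, linewidths=0, label=None)
    if highlight:
        sel = scores["compound_id"].isin(set(highlight)).to_numpy()
        if sel.any():
            ax.scatter(x[sel], y[sel], s=60, c="crimson", edgecolors="k",
                       linewidths=0.5, label=highlight_label, zorder=3)
            ax.legend(frameon=False, loc="lower right")
    lim = float(np.nanmax(np.abs(np.concatenate([x, y, [1.0]])))) * 1.08
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("d at 100 nM (percentage points)")
    ax.set_ylabel("d at 1 µM (percentage points)")
    ax.set_title("Differential viability: E41K-C481S − E41K")
    return fig


def plot_dose_response(
    data: pd.DataFrame,
    fits: Mapping[str, DoseResponseFit] | None = None,
    ax: plt.Axes | None = None,
) -> plt.Figure:
    """Per-line dose-response points with fitted 4PL curves on log-dose."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 4))
    else:
        fig = ax.figure
    for line, sub in data.groupby("line", sort=True):
        ax.semilogx(sub["dose_nM"], sub["viability_pct"], "o", ms=4, alpha=0.7, label=str(line))
        if fits and line in fits and fits[line].converged:
            f = fits[line]
            xs = np.geomspace(sub["dose_nM"].min(), sub["dose_nM"].max(), 100)
            ax.semilogx(xs, four_pl(xs, f.bottom, f.top, f.ic50, f.hill_slope), "-", lw=1.5)
    ax.set_xlabel("dose (nM)")
    ax.set_ylabel("viability (% of vehicle)")
    ax.legend(frameon=False)
    return fig
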