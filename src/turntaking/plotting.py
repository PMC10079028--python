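"""Plot helpers for the standard report figures.

All functions draw onto (and return) a matplotlib Axes so they compose;
file output is handled by the CLI's report command.
"""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .descriptives import fto_by_index, histogram_export

GROUP_COLOURS = {"ASD": "#3465a4", "CTR": "#4e9a06"}


def plot_fto_histogram(
    transfers: pd.DataFrame, bin_width_ms: float = 100.0, ax: Optional[plt.Axes] = None
) -> plt.Axes:
    """Per-group FTO histograms (proportion per centred bin)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for group, sub in transfers.groupby("group"):
        table = histogram_export(sub["fto_ms"], bin_width_ms)
        ax.step(
            table["centre_ms"], table["proportion"], where="mid",
            label=group, color=GROUP_COLOURS.get(group),
        )
    ax.axvline(0, ls=":", c="k", lw=0.8)
    ax.axvline(200, ls="--", c="grey", lw=0.8)
    ax.set_xlabel("FTO (ms)")
    ax.set_ylabel("proportion")
    ax.legend()
    return ax


def plot_fto_by_index(
    transfers: pd.DataFrame,
    max_index: int = 100,
    smooth_window: int = 11,
    detection_index: Optional[float] = None,
    resolution_index: Optional[float] = None,
    ax: Optional[plt.Axes] = None,
) -> plt.Axes:
    """Mean FTO by floor-transfer index, raw plus smoothed, per group."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    curves = fto_by_index(transfers, max_index=max_index, smooth_window=smooth_window)
    for group, sub in curves.groupby("group"):
        colour = GROUP_COLOURS.get(group)
        ax.plot(sub["index"], sub["mean_fto_ms"], lw=0.6, alpha=0.5, color=colour)
        ax.plot(sub["index"], sub["smoothed_ms"], lw=2.0, label=group, color=colour)
    for mark, label in ((detection_index, "detection"), (resolution_index, "resolution")):
        if mark is not None:
            ax.axvline(mark, ls="--", c="k", lw=0.8)
            ax.text(mark, ax.get_ylim()[1], f" {label}", va="top", fontsize=8)
    ax.set_xlabel("floor-transfer index")
    ax.set_ylabel("mean FTO (ms)")
    ax.legend()
    return ax
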