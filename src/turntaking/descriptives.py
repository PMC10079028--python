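"""Descriptive surfaces: cell summaries, modal bins, histograms,
leave-one-dyad-out robustness, and FTO-by-transition-index curves.

All operations take the flat floor-transfer table (one row per floor
transfer, within-overlaps already excluded) with columns ``fto_ms``,
``group``, ``dyad``, ``dialogue_id``, ``index`` and the epoch labels.

Histogram convention: centred half-open bins ``[c - w/2, c + w/2)`` with
centres on the integer multiples of the bin width, so a 100 ms grid
labels the bin [150, 250) as "200 ms" and represents a mode at 0
symmetrically. Ties for the modal bin return the lowest centre, flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

SCOPES = ("group", "dyad", "group_stage", "dyad_stage")


@dataclass(frozen=True)
class ModalBin:
    centre_ms: float
    tied: bool


def modal_bin(ftos: Sequence[float], bin_width_ms: float = 100.0) -> ModalBin:
    """Centre of the most populated centred bin; ties take the lowest."""
    values = np.asarray(ftos, dtype=float)
    if values.size == 0:
        raise ValueError("modal_bin requires at least one FTO value")
    centres = np.floor(values / bin_width_ms + 0.5) * bin_width_ms
    uniq, counts = np.unique(centres, return_counts=True)
    best = counts.max()
    winners = uniq[counts == best]
    return ModalBin(centre_ms=float(winners.min()), tied=winners.size > 1)


def histogram_export(
    ftos: Sequence[float], bin_width_ms: float = 100.0
) -> pd.DataFrame:
    """Bin table (centre, count, proportion) under the centred convention."""
    values = np.asarray(ftos, dtype=float)
    if values.size == 0:
        raise ValueError("histogram_export requires at least one FTO value")
    centres = np.floor(values / bin_width_ms + 0.5) * bin_width_ms
    uniq, counts = np.unique(centres, return_counts=True)
    return pd.DataFrame(
        {
            "centre_ms": uniq,
            "count": counts,
            "proportion": counts / counts.sum(),
        }
    )


def _cell_row(values: np.ndarray, bin_width_ms: float) -> dict:
    n = int(values.size)
    row = {
        "n": n,
        "mean_ms": float(values.mean()) if n else math.nan,
        "sd_ms": float(values.std(ddof=1)) if n >= 2 else math.nan,
        "median_ms": float(np.median(values)) if n else math.nan,
        "modal_bin_ms": math.nan,
        "modal_bin_tied": False,
    }
    if n:
        mb = modal_bin(values, bin_width_ms)
        row["modal_bin_ms"] = mb.centre_ms
        row["modal_bin_tied"] = mb.tied
    return row


def summarise(
    transfers: pd.DataFrame,
    scope: str = "group",
    stage_col: str = "epoch2",
    bin_width_ms: float = 100.0,
) -> pd.DataFrame:
    """Per-cell n / mean / sample SD / median / modal bin.

    ``scope`` is one of ``group``, ``dyad``, ``group_stage``,
    ``dyad_stage``; stage cells use ``stage_col`` (two- or three-way).
    """
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}, got {scope!r}")
    keys = {
        "group": ["group"],
        "dyad": ["group", "dyad"],
        "group_stage": ["group", stage_col],
        "dyad_stage": ["group", "dyad", stage_col],
    }[scope]
    rows = []
    for cell, sub in transfers.groupby(keys, sort=True, dropna=False):
        cell = cell if isinstance(cell, tuple) else (cell,)
        row = dict(zip(keys, cell))
        row.update(_cell_row(sub["fto_ms"].to_numpy(dtype=float), bin_width_ms))
        rows.append(row)
    return pd.DataFrame(rows)


def leave_one_dyad_out(
    transfers: pd.DataFrame, bin_width_ms: float = 100.0
) -> tuple[pd.DataFrame, float]:
    """Group summaries with each dyad omitted in turn.

    Returns the per-omission group summary table and the largest absolute
    change in any group mean relative to the full-corpus value.
    """
    full = summarise(transfers, "group", bin_width_ms=bin_width_ms).set_index("group")
    by_group = transfers.groupby("group")["dyad"].nunique()
    if (by_group < 2).any():
        raise ValueError("leave-one-dyad-out needs at least two dyads per group")
    rows = []
    max_dev = 0.0
    for dyad in sorted(transfers["dyad"].unique()):
        reduced = transfers[transfers["dyad"] != dyad]
        summary = summarise(reduced, "group", bin_width_ms=bin_width_ms)
        summary.insert(0, "omitted_dyad", dyad)
        for _, row in summary.iterrows():
            dev = abs(row["mean_ms"] - full.loc[row["group"], "mean_ms"])
            max_dev = max(max_dev, float(dev))
        rows.append(summary)
    return pd.concat(rows, ignore_index=True), max_dev


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge handling by window truncation."""
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if window == 1:
        return values.astype(float).copy()
    half = (window - 1) // 2
    out = np.empty(len(values), dtype=float)
    for i in range(len(values)):
        lo = max(0, i - half)
        hi = min(len(values), i + (window - half))
        chunk = values[lo:hi]
        out[i] = np.nanmean(chunk) if np.any(~np.isnan(chunk)) else np.nan
    return out


def fto_by_index(
    transfers: pd.DataFrame,
    max_index: int = 100,
    smooth_window: Optional[int] = None,
) -> pd.DataFrame:
    """Per-group mean FTO at each floor-transfer index.

    Index ``i`` averages over all dialogues of a group that reach at least
    ``i`` transfers. An optional moving-average smoother (odd window
    recommended) adds a ``smoothed_ms`` column; window 1 is the identity.
    """
    sub = transfers[transfers["index"] <= max_index]
    out = []
    for group, g in sub.groupby("group", sort=True):
        means = g.groupby("index")["fto_ms"].mean()
        idx = np.arange(1, int(means.index.max()) + 1) if len(means) else np.array([], int)
        curve = means.reindex(idx).to_numpy(dtype=float)
        frame = pd.DataFrame({"group": group, "index": idx, "mean_fto_ms": curve})
        if smooth_window is not None:
            frame["smoothed_ms"] = moving_average(curve, smooth_window)
        out.append(frame)
    if not out:
        return pd.DataFrame(columns=["group", "index", "mean_fto_ms"])
    return pd.concat(out, ignore_index=True)
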