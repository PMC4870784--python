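"""1-D immunofluorescence cross-section analysis.

Per-cell pixel-intensity profiles are smoothed with a centred 5-point
moving average; peaks are called where the smoothed signal strictly
increases over at least two successive observations into an apex, strictly
decreases over the next two, and the apex exceeds the channel's per-cell
mean intensity; overlaps between the two channels' peak extents are then
counted to quantify co-localisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PeakCall:
    """One called peak: apex index and half-open extent [start, end)."""

    cell_id: str
    channel: str
    apex: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start <= self.apex < self.end:
            raise ValueError("apex must lie within the extent")


def smooth(values: np.ndarray, window: int = 5) -> np.ndarray:
    """Centred moving average; edges average over the shrinking window that
    fits (the mean of the available neighbours)."""
    values = np.asarray(values, dtype=float)
    if len(values) < window:
        raise ValueError(f"profile shorter than smoothing window ({window})")
    half = window // 2
    kernel = np.ones(window)
    sums = np.convolve(values, kernel, mode="same")
    counts = np.convolve(np.ones_like(values), kernel, mode="same")
    # np.convolve 'same' centres even windows off by one; recompute edges
    out = sums / counts
    for i in range(half):
        out[i] = values[: i + half + 1].mean()
        out[-(i + 1)] = values[-(i + half + 1):].mean()
    return out


def apex_mask(values: np.ndarray, channel_mean: np.ndarray | float,
              min_rise: int = 2, min_fall: int = 2) -> np.ndarray:
    """Boolean apex mask for one profile or a batch (position on last axis).

    Index i is an apex iff the values strictly increase over ``min_rise``
    successive steps into i, strictly decrease over the ``min_fall`` steps
    after i, and the value at i exceeds the channel mean.  Plateaus break
    runs (strict inequalities).
    """
    v = np.asarray(values, dtype=float)
    d = np.diff(v, axis=-1) > 0          # d[..., j]: step j -> j+1 rises
    n = v.shape[-1]
    mask = np.zeros(v.shape, dtype=bool)
    if n < min_rise + min_fall + 1:
        return mask
    core = np.ones(v.shape[:-1] + (n - min_rise - min_fall,), dtype=bool)
    for k in range(min_rise):
        core &= d[..., k: k + core.shape[-1]]
    for k in range(min_fall):
        core &= ~d[..., min_rise + k: min_rise + k + core.shape[-1]] \
            & (np.diff(v, axis=-1) != 0)[..., min_rise + k:
                                         min_rise + k + core.shape[-1]]
    mask[..., min_rise: n - min_fall] = core
    mean = np.asarray(channel_mean, dtype=float)
    mask &= v > mean[..., None] if mean.ndim else v > mean
    return mask


def find_peaks(
    smoothed: np.ndarray,
    channel_mean: float,
    min_rise: int = 2,
    min_fall: int = 2,
    cell_id: str = "",
    channel: str = "",
) -> list[PeakCall]:
    """Rule-based peak calling on a smoothed profile.

    Apexes follow :func:`apex_mask`.  The extent of a peak is the maximal
    strictly-monotone run around its apex; where consecutive extents would
    overlap they are resolved left-to-right by truncating the later start.
    """
    v = np.asarray(smoothed, dtype=float)
    n = len(v)
    calls: list[PeakCall] = []
    for i in np.flatnonzero(apex_mask(v, channel_mean, min_rise, min_fall)):
        i = int(i)
        start = i
        while start > 0 and v[start - 1] < v[start]:
            start -= 1
        end = i
        while end < n - 1 and v[end + 1] < v[end]:
            end += 1
        end += 1  # half-open
        if calls and calls[-1].channel == channel and start < calls[-1].end:
            start = calls[-1].end
        calls.append(PeakCall(cell_id, channel, i, start, end))
    return calls


def call_profile_table(profiles: pd.DataFrame, window: int = 5,
                       threshold_on_smoothed: bool = True) -> pd.DataFrame:
    """Smooth and call peaks for every (cell, channel) profile in a table.

    ``profiles`` is long-form with columns cell_id, channel, index,
    intensity (ordered by index).  The channel mean used as the apex
    threshold is computed per cell on the smoothed signal by default (or
    the raw signal when ``threshold_on_smoothed`` is off).
    """
    rows = []
    for (cell, channel), grp in profiles.groupby(["cell_id", "channel"]):
        values = grp.sort_values("index")["intensity"].to_numpy()
        sm = smooth(values, window)
        mean = float(sm.mean() if threshold_on_smoothed else values.mean())
        for call in find_peaks(sm, mean, cell_id=str(cell), channel=str(channel)):
            rows.append({"cell_id": call.cell_id, "channel": call.channel,
                         "apex": call.apex, "start": call.start,
                         "end": call.end})
    return pd.DataFrame(rows, columns=["cell_id", "channel", "apex",
                                       "start", "end"])


def count_overlaps(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> dict:
    """Count channel-A peaks whose extent intersects any channel-B extent.

    Extents are half-open index intervals, compared within each cell.
    Returns per-cell counts and the pooled overlap fraction.
    """
    per_cell = []
    cells = sorted(set(calls_a["cell_id"]) | set(calls_b["cell_id"]))
    for cell in cells:
        a = calls_a[calls_a["cell_id"] == cell]
        b = calls_b[calls_b["cell_id"] == cell]
        n_overlap = 0
        for pa in a.itertuples(index=False):
            if any(pa.start < pb.end and pb.start < pa.end
                   for pb in b.itertuples(index=False)):
                n_overlap += 1
        per_cell.append({"cell_id": cell, "n_peaks_a": len(a),
                         "n_peaks_b": len(b), "n_overlapping": n_overlap})
    df = pd.DataFrame(per_cell)
    total_a = int(df["n_peaks_a"].sum()) if len(df) else 0
    total_ov = int(df["n_overlapping"].sum()) if len(df) else 0
    return {"per_cell": df,
            "pooled_fraction": total_ov / total_a if total_a else np.nan,
            "n_peaks_a": total_a, "n_overlapping": total_ov}
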