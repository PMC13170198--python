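"""Population response curves (PRCs) and their slope dynamics.

A PRC fixes the presented direction and plots activity across neurons grouped
by their preferred direction: for each trial and time bin, neurons are grouped
by preferred direction, averaged within group, re-indexed by the wrapped
offset (preferred - presented), and averaged over trials (and, unless a
per-direction view is requested, over presented directions).  The slope of the
zero-centered PRC over offsets -180..0 (pair-averaging +-45, +-90, +-135)
summarizes direction selectivity: 0 means none, larger means sharper.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ._angles import DIRECTION_SET
from .epochs import epoch_tensor
from .tuning import ALIGNED_OFFSETS, _SLOPE_W, compute_tuning


@dataclasses.dataclass
class PRCTensor:
    """Offset x time population response, plus the per-direction view."""

    offsets: np.ndarray  # ALIGNED_OFFSETS (-180..135; 180 is the same bin as -180)
    times: np.ndarray  # bin centers, s relative to onset
    values: np.ndarray  # 8 offsets x bins (NaN where a preferred bin is empty)
    by_direction: np.ndarray  # 8 presented dirs x 8 offsets x bins
    n_trials: int
    neurons_per_bin: np.ndarray  # count of neurons per preferred-direction bin
    condition: str


def preferred_direction_map(
    traces, trials: pd.DataFrame, frame_rate: float, condition: str,
    correct_only: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-neuron preferred direction (argmax of the 4-s tuning curve).

    Returns (preferred_direction degrees, tie_flag); ties resolve to the
    lowest direction.
    """
    tc = compute_tuning(traces, trials, frame_rate, condition, correct_only=correct_only)
    return tc.preferred_direction, tc.tie_flag


def build_prc(
    traces,
    trials: pd.DataFrame,
    frame_rate: float,
    pref_map: np.ndarray,
    condition: str,
    correct_only: bool = True,
    t_start: float = -0.5,
    t_stop: float = 4.0,
    decimate: int = 1,
    directions=DIRECTION_SET,
    neuron_subset: np.ndarray | None = None,
) -> PRCTensor:
    """Construct the zero-centered PRC tensor for one variance condition.

    ``pref_map`` gives each neuron's preferred direction in degrees (from
    ``preferred_direction_map``).  Empty preferred-direction bins propagate as
    NaN at the offsets they would fill.
    """
    dirs = np.asarray(directions, float)
    sel = trials["variance_condition"] == condition
    if correct_only:
        sel &= trials["correct"].astype(bool)
    sub = trials[sel]
    if len(sub) == 0:
        raise ValueError(f"no trials in condition {condition!r}")
    tensor, times = epoch_tensor(traces, sub, frame_rate, t_start, t_stop, decimate)
    pref_map = np.asarray(pref_map, float)
    if neuron_subset is not None:
        tensor = tensor[:, neuron_subset, :]
        pref_map = pref_map[neuron_subset]
    if pref_map.size != tensor.shape[1]:
        raise ValueError("pref_map must cover all neurons")
    # group-average matrix: 8 pref bins x neurons (rows of empty bins -> NaN)
    G = np.full((8, pref_map.size), 0.0)
    counts = np.zeros(8)
    pref_idx = np.searchsorted(dirs, pref_map)
    for g in range(8):
        m = pref_idx == g
        counts[g] = m.sum()
        if counts[g] > 0:
            G[g, m] = 1.0 / counts[g]
    n_bins = tensor.shape[2]
    d_idx = np.searchsorted(dirs, sub["mean_direction"].to_numpy())
    roll = np.arange(8)
    sums = np.zeros((8, 8, n_bins))  # presented dir x offset x time
    n_per_dir = np.zeros(8)
    for tr in range(tensor.shape[0]):
        curves = G @ tensor[tr]  # 8 pref groups x bins
        rolled = curves[(d_idx[tr] + roll) % 8]  # offsets 0,45,...,315
        sums[d_idx[tr]] += rolled
        n_per_dir[d_idx[tr]] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        by_dir = sums / n_per_dir[:, None, None]
    empty = counts == 0
    if empty.any():
        # offset cells fed by an empty preferred bin carry NaN
        for d in range(8):
            for j in range(8):
                if empty[(d + j) % 8]:
                    by_dir[d, j, :] = np.nan
    # average over presented directions (trial-count weighted)
    w = n_per_dir / n_per_dir.sum()
    values = np.einsum("d,djt->jt", w, by_dir)
    # reorder offset axis 0,45,...,315 -> -180..135
    order = np.array([4, 5, 6, 7, 0, 1, 2, 3])
    return PRCTensor(
        offsets=ALIGNED_OFFSETS.copy(),
        times=times,
        values=values[order],
        by_direction=by_dir[:, order, :],
        n_trials=int(len(sub)),
        neurons_per_bin=counts,
        condition=condition,
    )


def slope_timecourse(values: np.ndarray) -> np.ndarray:
    """Slope per time bin of an offsets(-180..135) x bins array.

    Pairs (+-45, +-90, +-135) are averaged; the line runs over offsets
    -180..0.  Bins touching a NaN offset return NaN.
    """
    v = np.asarray(values, float)
    y = np.stack(
        [
            v[0],  # -180
            (v[1] + v[7]) / 2.0,  # +-135
            (v[2] + v[6]) / 2.0,  # +-90
            (v[3] + v[5]) / 2.0,  # +-45
            v[4],  # 0
        ]
    )
    return _SLOPE_W @ y


def prc_slope(prc: PRCTensor) -> pd.DataFrame:
    """PRC slope per time bin (positive = population peaks at the presented
    direction); NaN rows mark bins skipped because an offset cell was empty."""
    slopes = slope_timecourse(prc.values)
    return pd.DataFrame(
        {"time": prc.times, "slope": slopes, "condition": prc.condition}
    )


def subset_prc(
    traces,
    trials: pd.DataFrame,
    frame_rate: float,
    tuning_slopes: np.ndarray,
    condition: str,
    percents=(10, 50, 95, 100),
    correct_only: bool = True,
    decimate: int = 1,
) -> pd.DataFrame:
    """Mean stimulus-window PRC slope using the bottom p% of neurons.

    Neurons are rank-ordered by their single-neuron tuning-curve slopes; the
    bottom p% (least tuned) are kept, the preferred-direction map is
    re-derived within the subset, and the PRC slope is averaged over 0-4 s.
    """
    slopes_rank = np.argsort(np.asarray(tuning_slopes, float), kind="stable")
    n = slopes_rank.size
    rows = []
    for p in percents:
        k = int(np.ceil(p / 100.0 * n))
        subset = np.sort(slopes_rank[:k])
        if subset.size < 8:
            raise ValueError(f"bottom {p}% leaves {subset.size} neurons; need >= 8")
        sub_traces = traces[subset]
        pref, _ = preferred_direction_map(
            sub_traces, trials, frame_rate, condition, correct_only
        )
        prc = build_prc(
            sub_traces, trials, frame_rate,
            pref_map=pref, condition=condition, correct_only=correct_only,
            decimate=decimate,
        )
        s = slope_timecourse(prc.values)[prc.times >= 0]
        # a subset too small to occupy all 8 preferred bins yields NaN slopes
        mean_slope = float(np.nanmean(s)) if np.isfinite(s).any() else float("nan")
        rows.append(
            {
                "subset_percent": p,
                "n_neurons": int(subset.size),
                "mean_slope": mean_slope,
            }
        )
    return pd.DataFrame(rows)
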