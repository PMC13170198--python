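"""Trial-aligned views of the neurons x frames trace matrix."""

from __future__ import annotations

import numpy as np
import pandas as pd


def epoch_tensor(
    traces: np.ndarray,
    trials: pd.DataFrame,
    frame_rate: float,
    t_start: float = -0.5,
    t_stop: float = 4.0,
    decimate: int = 1,
):
    """Cut trial epochs out of the trace matrix.

    Returns ``(tensor, times)`` with tensor shaped trials x neurons x bins and
    ``times`` the bin centers in seconds relative to stimulus onset.  With
    ``decimate > 1`` consecutive groups of frames are averaged into wider bins.
    """
    traces = np.atleast_2d(np.asarray(traces, float))
    onsets = trials["onset_frame"].to_numpy(dtype=int)
    f0 = int(np.floor(t_start * frame_rate))
    f1 = int(np.round(t_stop * frame_rate))
    idx = np.arange(f0, f1)
    if onsets.min() + f0 < 0 or onsets.max() + f1 > traces.shape[1]:
        raise ValueError("epoch window exceeds trace bounds for some trial")
    cut = traces[:, onsets[:, None] + idx[None, :]]  # neurons x trials x frames
    tensor = np.transpose(cut, (1, 0, 2))
    times = (idx + 0.5) / frame_rate
    if decimate > 1:
        n_bins = tensor.shape[2] // decimate
        tensor = tensor[:, :, : n_bins * decimate].reshape(
            tensor.shape[0], tensor.shape[1], n_bins, decimate
        ).mean(axis=3)
        times = times[: n_bins * decimate].reshape(n_bins, decimate).mean(axis=1)
    return tensor, times


def trial_window_mean(
    traces: np.ndarray,
    trials: pd.DataFrame,
    frame_rate: float,
    t_start: float = 0.0,
    t_stop: float = 4.0,
) -> np.ndarray:
    """Per-trial mean over a time window: trials x neurons."""
    tensor, _ = epoch_tensor(traces, trials, frame_rate, t_start, t_stop)
    return tensor.mean(axis=2)
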