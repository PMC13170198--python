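"""dF/F trace conditioning downstream of source extraction.

Two steps, matching standard one-photon miniscope practice:

1. ``clean_traces`` -- subtract the 8th percentile within a centered sliding
   window of 900 frames (slow-drift removal), then Savitzky-Golay smoothing
   (order 3, frame length 11).
2. ``detect_events_and_qc`` -- per neuron, a noise threshold of 3x the
   interquartile range of the negative deflections (mirrored to a symmetric
   sample); values above threshold are retained, the rest zeroed.  Neurons
   whose negatively deflected events exceed 5% of the positively deflected
   ones fail QC.

An "event" is a maximal run of consecutive supra-threshold frames.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter


@dataclasses.dataclass
class EventDetectionResult:
    """Thresholded event traces plus per-neuron QC bookkeeping."""

    events: np.ndarray  # neurons x frames, zero below threshold
    threshold: np.ndarray  # per-neuron noise threshold (dF/F)
    n_positive_events: np.ndarray
    n_negative_events: np.ndarray
    qc_pass: np.ndarray  # boolean per neuron
    no_negative_samples: np.ndarray  # neurons whose threshold fell back to 0

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neuron_id": np.arange(self.events.shape[0]),
                "threshold": self.threshold,
                "n_pos": self.n_positive_events,
                "n_neg": self.n_negative_events,
                "qc_pass": self.qc_pass,
            }
        )


def rolling_percentile_baseline(
    traces: np.ndarray, window_frames: int = 900, percentile: float = 8.0
) -> np.ndarray:
    """Centered sliding-window percentile per neuron, truncated at the edges."""
    traces = np.atleast_2d(np.asarray(traces, float))
    df = pd.DataFrame(traces.T)
    base = (
        df.rolling(window=window_frames, center=True, min_periods=1)
        .quantile(percentile / 100.0)
        .to_numpy()
        .T
    )
    return base


def clean_traces(
    raw: np.ndarray,
    window_frames: int = 900,
    percentile: float = 8.0,
    sg_order: int = 3,
    sg_len: int = 11,
) -> np.ndarray:
    """Baseline-subtracted, smoothed dF/F (same shape as input)."""
    raw = np.atleast_2d(np.asarray(raw, float))
    if raw.shape[1] < sg_len:
        raise ValueError(f"trace length {raw.shape[1]} shorter than smoothing length {sg_len}")
    debased = raw - rolling_percentile_baseline(raw, window_frames, percentile)
    return savgol_filter(debased, window_length=sg_len, polyorder=sg_order, axis=1)


def _count_events(trace: np.ndarray, threshold: float) -> int:
    """Number of maximal runs of consecutive frames strictly above threshold."""
    above = trace > threshold
    if not above.any():
        return 0
    return int(np.count_nonzero(np.diff(np.concatenate(([False], above)).astype(int)) == 1))


def detect_events_and_qc(
    clean: np.ndarray, k: float = 3.0, qc_ratio: float = 0.05
) -> EventDetectionResult:
    """Threshold events at k x IQR of mirrored negative deflections; QC neurons.

    A trace with no negative samples has an undefined noise estimate; it is
    flagged (``no_negative_samples``) and passed through with threshold 0,
    retaining all strictly positive values.
    """
    clean = np.atleast_2d(np.asarray(clean, float))
    n_neurons, _ = clean.shape
    threshold = np.zeros(n_neurons)
    n_pos = np.zeros(n_neurons, dtype=int)
    n_neg = np.zeros(n_neurons, dtype=int)
    no_neg = np.zeros(n_neurons, dtype=bool)
    events = np.zeros_like(clean)
    for i in range(n_neurons):
        x = clean[i]
        neg = x[x < 0]
        if neg.size == 0:
            no_neg[i] = True
            thr = 0.0
        else:
            mirrored = np.concatenate([neg, -neg])
            q75, q25 = np.percentile(mirrored, [75, 25])
            thr = k * (q75 - q25)
        threshold[i] = thr
        events[i] = np.where(x > thr, x, 0.0)
        n_pos[i] = _count_events(x, thr)
        n_neg[i] = _count_events(-x, thr)
    qc_pass = n_neg <= qc_ratio * n_pos
    return EventDetectionResult(
        events=events,
        threshold=threshold,
        n_positive_events=n_pos,
        n_negative_events=n_neg,
        qc_pass=qc_pass,
        no_negative_samples=no_neg,
    )
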