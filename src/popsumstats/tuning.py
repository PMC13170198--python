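"""Single-cell direction tuning: curves, DSI, permutation selectivity,
linear-summation simulation, cross-condition similarity, peak confusion.

A neuron's tuning curve is the 8-direction vector of AUC responses: the
trial-averaged 0-4 s post-onset signal, summarized as its mean times the
stimulus duration.  Direction-selective neurons satisfy both DSI > 0.4 and a
zero-centered tuning-curve slope above the 95th percentile of a
direction-label-shuffled null.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import binom, pearsonr

from ._angles import DIRECTION_SET
from .epochs import trial_window_mean
from .stats import bh_fdr

#: zero-centered offsets used for presentation, in curve-roll order 0,45,...,315
ALIGNED_OFFSETS = np.array([-180.0, -135.0, -90.0, -45.0, 0.0, 45.0, 90.0, 135.0])

# OLS weights for the slope over the 5 pair-averaged offsets (-180..0)
_SLOPE_X = np.array([-180.0, -135.0, -90.0, -45.0, 0.0])
_SLOPE_W = (_SLOPE_X - _SLOPE_X.mean()) / np.sum((_SLOPE_X - _SLOPE_X.mean()) ** 2)


@dataclasses.dataclass
class TuningCurves:
    """Per-neuron 8-direction responses and derived statistics."""

    directions: np.ndarray  # the 8 mean directions (degrees)
    responses: np.ndarray  # neurons x 8 AUC responses
    condition: str
    preferred_direction: np.ndarray  # degrees (argmax, ties -> lowest, flagged)
    tie_flag: np.ndarray
    dsi: np.ndarray
    slope: np.ndarray  # response units per degree
    selective: np.ndarray | None = None
    null_slope_95: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return self.responses.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.responses, columns=[f"resp_{d:g}" for d in self.directions]
        )
        df.insert(0, "neuron_id", np.arange(self.n_neurons))
        df["condition"] = self.condition
        df["preferred_direction"] = self.preferred_direction
        df["dsi"] = self.dsi
        df["slope"] = self.slope
        if self.selective is not None:
            df["selective"] = self.selective
            df["null_slope_95"] = self.null_slope_95
        return df


def trial_aucs(
    traces, trials, frame_rate, stim_duration: float = 4.0
) -> np.ndarray:
    """Per-trial AUC (mean x duration of the 0-4 s signal): trials x neurons."""
    return trial_window_mean(traces, trials, frame_rate, 0.0, stim_duration) * stim_duration


def _group_mean_responses(X: np.ndarray, labels: np.ndarray, directions) -> np.ndarray:
    """Mean response per direction: neurons x 8.  Errors on empty cells."""
    out = np.empty((X.shape[1], len(directions)))
    for j, d in enumerate(directions):
        m = labels == d
        if not m.any():
            raise ValueError(f"no trials for direction {d}")
        out[:, j] = X[m].mean(axis=0)
    return out


def dsi(responses: np.ndarray) -> np.ndarray:
    """(R_pref - R_antipref) / R_pref per neuron; NaN where R_pref == 0."""
    R = np.atleast_2d(np.asarray(responses, float))
    pref_idx = R.argmax(axis=1)
    anti_idx = (pref_idx + R.shape[1] // 2) % R.shape[1]
    rp = R[np.arange(len(R)), pref_idx]
    ra = R[np.arange(len(R)), anti_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(rp != 0, (rp - ra) / rp, np.nan)
    return out


def zero_centered(responses: np.ndarray, pref_idx: np.ndarray) -> np.ndarray:
    """Roll each curve so its preferred direction sits at offset 0.

    Column j of the result is the response at offset j*45 degrees from the
    preferred direction (wrapped; see ALIGNED_OFFSETS for the -180..135 view).
    """
    R = np.atleast_2d(np.asarray(responses, float))
    idx = (np.atleast_1d(pref_idx)[:, None] + np.arange(R.shape[1])[None, :]) % R.shape[1]
    return np.take_along_axis(R, idx, axis=1)


def tuning_slope(responses: np.ndarray, pref_idx: np.ndarray | None = None) -> np.ndarray:
    """Least-squares slope of the zero-centered curve over offsets -180..0.

    Offset pairs (+-45, +-90, +-135) are averaged; -180 and 0 stay singletons.
    Positive slope means the curve rises toward the preferred direction.
    """
    R = np.atleast_2d(np.asarray(responses, float))
    if pref_idx is None:
        pref_idx = R.argmax(axis=1)
    z = zero_centered(R, pref_idx)  # columns: offsets 0,45,...,315
    y = np.stack(
        [
            z[:, 4],  # -180
            (z[:, 3] + z[:, 5]) / 2.0,  # +-135
            (z[:, 2] + z[:, 6]) / 2.0,  # +-90
            (z[:, 1] + z[:, 7]) / 2.0,  # +-45
            z[:, 0],  # 0
        ],
        axis=1,
    )
    return y @ _SLOPE_W


def compute_tuning(
    traces,
    trials: pd.DataFrame,
    frame_rate: float,
    condition: str,
    correct_only: bool = True,
    stim_duration: float = 4.0,
    directions=DIRECTION_SET,
) -> TuningCurves:
    """Tuning curves for one variance condition from the 0-4 s AUC responses."""
    sel = trials["variance_condition"] == condition
    if correct_only:
        sel &= trials["correct"].astype(bool)
    sub = trials[sel]
    X = trial_aucs(traces, sub, frame_rate, stim_duration)
    labels = sub["mean_direction"].to_numpy()
    R = _group_mean_responses(X, labels, directions)
    pref_idx = R.argmax(axis=1)
    ties = (R == R.max(axis=1, keepdims=True)).sum(axis=1) > 1
    dirs = np.asarray(directions, float)
    return TuningCurves(
        directions=dirs,
        responses=R,
        condition=condition,
        preferred_direction=dirs[pref_idx],
        tie_flag=ties,
        dsi=dsi(R),
        slope=tuning_slope(R, pref_idx),
    )


def _shuffled_slopes(
    X: np.ndarray, labels: np.ndarray, directions, n_perm: int, rng
) -> np.ndarray:
    """Null tuning slopes from direction-label shuffles: n_perm x neurons."""
    dirs = np.asarray(directions, float)
    lab_idx = np.searchsorted(dirs, labels)
    counts = np.bincount(lab_idx, minlength=len(dirs)).astype(float)
    out = np.empty((n_perm, X.shape[1]))
    for p in range(n_perm):
        perm = rng.permutation(lab_idx)
        D = np.zeros((len(dirs), len(perm)))
        D[perm, np.arange(len(perm))] = 1.0
        R = (D @ X) / counts[:, None]  # 8 x neurons
        out[p] = tuning_slope(R.T)
    return out


def classify_selective(
    curves: TuningCurves,
    traces,
    trials: pd.DataFrame,
    frame_rate: float,
    dsi_thresh: float = 0.4,
    n_perm: int = 5000,
    pct: float = 95.0,
    rng: np.random.Generator | None = None,
    correct_only: bool = True,
    stim_duration: float = 4.0,
) -> TuningCurves:
    """Flag neurons as direction-selective: DSI > 0.4 AND slope above the
    per-neuron 95th-percentile null from direction-label shuffles."""
    if n_perm < 100:
        raise ValueError("n_perm < 100 makes the null percentile unstable")
    rng = rng or np.random.default_rng()
    sel = trials["variance_condition"] == curves.condition
    if correct_only:
        sel &= trials["correct"].astype(bool)
    sub = trials[sel]
    X = trial_aucs(traces, sub, frame_rate, stim_duration)
    labels = sub["mean_direction"].to_numpy()
    null = _shuffled_slopes(X, labels, curves.directions, n_perm, rng)
    null95 = np.percentile(null, pct, axis=0)
    selective = (curves.dsi > dsi_thresh) & (curves.slope > null95)
    selective &= ~np.isnan(curves.dsi)
    return dataclasses.replace(curves, selective=selective, null_slope_95=null95)


# ---------------------------------------------------------------------------
# Linear-summation simulation of heterogeneous tuning
# ---------------------------------------------------------------------------

def _window_average_curves(responses: np.ndarray, range_deg: float) -> np.ndarray:
    """Average each 8-point circular curve over a uniform window of width r.

    The curve is treated as band-limited (trigonometric interpolation of the
    8 samples); averaging over a window multiplies harmonic m by
    sin(m r/2)/(m r/2), which is exact for the cosine components and reduces
    to the identity at r = 0 and to the circular mean at r = 360.
    """
    R = np.atleast_2d(np.asarray(responses, float))
    if range_deg == 0:
        return R.copy()
    F = np.fft.rfft(R, axis=1)
    m = np.arange(F.shape[1])
    x = m * np.deg2rad(range_deg) / 2.0
    factor = np.ones_like(x)
    nz = x != 0
    factor[nz] = np.sin(x[nz]) / x[nz]
    return np.fft.irfft(F * factor[None, :], n=R.shape[1], axis=1)


def simulate_het_tuning(
    hom_curves: TuningCurves,
    range_deg: float,
    n_match: int,
    n_resample: int = 1000,
    rng: np.random.Generator | None = None,
    selective_only: bool = True,
) -> dict:
    """Predict heterogeneous tuning from linear summation of local motion.

    Each resample draws ``n_match`` homogeneous tuning curves (with
    replacement), transforms each by averaging it over a uniform direction
    window of width ``range_deg``, aligns curves on the homogeneous preferred
    direction, and averages.  Returns the mean aligned curve (offsets
    ALIGNED_OFFSETS) and the distribution of peak amplitudes (aligned peak
    minus curve mean) across resamples.
    """
    rng = rng or np.random.default_rng()
    R = hom_curves.responses
    pref_idx = np.searchsorted(hom_curves.directions, hom_curves.preferred_direction)
    if selective_only and hom_curves.selective is not None:
        keep = hom_curves.selective
        R, pref_idx = R[keep], pref_idx[keep]
    if R.shape[0] == 0:
        raise ValueError("no homogeneous curves to resample")
    transformed = _window_average_curves(R, range_deg)
    aligned = zero_centered(transformed, pref_idx)  # columns: offsets 0,45,...
    # reorder columns to ALIGNED_OFFSETS (-180..135)
    order = np.array([4, 5, 6, 7, 0, 1, 2, 3])
    aligned = aligned[:, order]
    curves = np.empty((n_resample, 8))
    peaks = np.empty(n_resample)
    for r in range(n_resample):
        pick = rng.integers(0, aligned.shape[0], size=n_match)
        mean_curve = aligned[pick].mean(axis=0)
        curves[r] = mean_curve
        peaks[r] = mean_curve[4] - mean_curve.mean()  # offset 0 minus curve mean
    return {
        "offsets": ALIGNED_OFFSETS.copy(),
        "mean_curve": curves.mean(axis=0),
        "peak_amplitudes": peaks,
    }


# ---------------------------------------------------------------------------
# Cross-condition similarity
# ---------------------------------------------------------------------------

def cross_condition_correlation(
    responses_a: np.ndarray,
    responses_b: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    trial_aucs_b: np.ndarray | None = None,
    labels_b: np.ndarray | None = None,
    directions=DIRECTION_SET,
) -> tuple[float, float]:
    """Pearson R between concatenated 8-direction response arrays + perm p.

    The null shuffles condition-B direction labels at the trial level when
    per-trial responses are supplied; otherwise it permutes each neuron's
    8 responses independently.
    """
    A = np.asarray(responses_a, float).ravel()
    B = np.asarray(responses_b, float)
    if B.shape[0] < 2:
        raise ValueError("need at least 2 neurons")
    r_obs = pearsonr(A, B.ravel()).statistic
    rng = rng or np.random.default_rng()
    count = 0
    for _ in range(n_perm):
        if trial_aucs_b is not None and labels_b is not None:
            perm_labels = rng.permutation(labels_b)
            Bp = _group_mean_responses(trial_aucs_b, perm_labels, directions)
        else:
            Bp = np.take_along_axis(
                B, np.argsort(rng.random(B.shape), axis=1), axis=1
            )
        if abs(pearsonr(A, Bp.ravel()).statistic) >= abs(r_obs):
            count += 1
    return float(r_obs), (1 + count) / (1 + n_perm)


# ---------------------------------------------------------------------------
# Peak confusion matrix
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PeakConfusionMatrix:
    """8x8 proportions (rows het peak, cols hom peak) + per-cell significance."""

    directions: np.ndarray
    proportions: np.ndarray  # 8 x 8, sums to 1
    p_values: np.ndarray
    significant: np.ndarray  # BH-FDR mask
    n_neurons: int


def _peaks(X: np.ndarray, labels: np.ndarray, directions) -> np.ndarray:
    return _group_mean_responses(X, labels, directions).argmax(axis=1)


def peak_confusion(
    aucs_hom: np.ndarray,
    labels_hom: np.ndarray,
    aucs_het: np.ndarray,
    labels_het: np.ndarray,
    n_perm: int = 5000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    directions=DIRECTION_SET,
) -> PeakConfusionMatrix:
    """Proportion of neurons peaking at each (het, hom) direction pair.

    Significance per cell against trial-label-shuffled surrogates (within
    condition), BH-FDR corrected across the 64 cells.
    """
    rng = rng or np.random.default_rng()
    dirs = np.asarray(directions, float)
    n_neurons = aucs_hom.shape[1]
    peaks_hom = _peaks(aucs_hom, labels_hom, dirs)
    peaks_het = _peaks(aucs_het, labels_het, dirs)
    obs = np.zeros((8, 8))
    np.add.at(obs, (peaks_het, peaks_hom), 1.0)
    obs /= n_neurons
    exceed = np.zeros((8, 8))
    for _ in range(n_perm):
        ph = _peaks(aucs_hom, rng.permutation(labels_hom), dirs)
        pt = _peaks(aucs_het, rng.permutation(labels_het), dirs)
        surr = np.zeros((8, 8))
        np.add.at(surr, (pt, ph), 1.0)
        exceed += surr / n_neurons >= obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    sig, _ = bh_fdr(pvals.ravel(), alpha=alpha)
    return PeakConfusionMatrix(
        directions=dirs,
        proportions=obs,
        p_values=pvals,
        significant=sig.reshape(8, 8),
        n_neurons=n_neurons,
    )


def overlap_significance(
    selective_a: np.ndarray, selective_b: np.ndarray
) -> tuple[int, float]:
    """Is the overlap of two selective sets above the independence null?

    Binomial test of |A and B| against n * p(A) * p(B); returns the overlap
    count and the one-sided (greater) p-value.
    """
    a = np.asarray(selective_a, bool)
    b = np.asarray(selective_b, bool)
    n = a.size
    k = int((a & b).sum())
    p0 = a.mean() * b.mean()
    return k, float(binom.sf(k - 1, n, p0))
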