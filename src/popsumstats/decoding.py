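"""Trial-resolved decoding of mean direction, variance, and category.

Inverted encoding model (IEM)
-----------------------------
Eight channel basis functions b_j(theta) = cos^6(Delta_j / 2) (half sinusoid
raised to the sixth power, Delta_j the wrapped difference from the j-th
direction) define a forward model B = W C.  Weights are estimated by OLS,
W_hat = B1 C1' (C1 C1')^-1, and inverted on held-out data,
C2_hat = (W_hat' W_hat)^-1 W_hat' B2.  Channel responses are zero-centered on
the presented direction (CTF) and summarized by a slope: offsets +-45, +-90,
+-135 share x positions -45, -90, -135 (duplicated, not averaged) and an OLS
line runs over the eight points from -180 to 0.

SVM decoders
------------
Linear-kernel binary classifiers (unit regularization, class-weight
balancing) for variance (hom vs het) and category (left vs right), trained
and tested per time bin.  Within-category (WCD) vs between-category (BCD)
discrimination contrasts direction pairs 90 deg apart that stay within, or
cross, the learned boundary, under repeated stratified 5-fold CV on
homogeneous trials, with hom-trained decoders transferred to heterogeneous
trials.  Temporal generalization trains at one bin and tests at every other.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from ._angles import DIRECTION_SET, wrap180
from .epochs import epoch_tensor

#: x positions for the CTF slope regression, in ALIGNED_OFFSETS order
#: (-180, -135, -90, -45, 0, 45, 90, 135) with the positive offsets reflected.
_CTF_X = np.array([-180.0, -135.0, -90.0, -45.0, 0.0, -45.0, -90.0, -135.0])
_CTF_W = (_CTF_X - _CTF_X.mean()) / np.sum((_CTF_X - _CTF_X.mean()) ** 2)


def make_basis(thetas, centers=DIRECTION_SET, power: int = 6) -> np.ndarray:
    """Channel basis matrix: channels x len(thetas).

    Each basis function peaks at 1 on its center and vanishes only at the
    opposite direction; at 45 deg spacing the eight functions tile the circle
    (their sum is constant in theta).
    """
    thetas = np.atleast_1d(np.asarray(thetas, float))
    centers = np.asarray(centers, float)
    delta = wrap180(thetas[None, :] - centers[:, None])
    return np.cos(np.deg2rad(delta) / 2.0) ** power


class InvertedEncodingModel:
    """Forward encoding model over the 8-direction channel basis."""

    def __init__(self, centers=DIRECTION_SET, power: int = 6):
        self.centers = np.asarray(centers, float)
        self.power = power
        self.weights: np.ndarray | None = None

    def design(self, directions) -> np.ndarray:
        """C matrix (channels x trials) for labeled trial directions."""
        return make_basis(directions, self.centers, self.power)

    def fit(self, B1: np.ndarray, C1: np.ndarray) -> "InvertedEncodingModel":
        """OLS weight estimate W_hat = B1 C1' (C1 C1')^+ (neurons x channels).

        The cos^6 basis contains direction harmonics 0-3 only, so the eight
        channel profiles span a 7-dimensional space and C1 C1' is always
        rank 7: the normal equations are solved with the pseudoinverse, which
        is exact on that span.  Training still requires all 8 distinct
        directions so every channel is anchored.
        """
        B1 = np.asarray(B1, float)
        C1 = np.asarray(C1, float)
        n_distinct = np.unique(np.round(C1.T, 12), axis=0).shape[0]
        if n_distinct < C1.shape[0]:
            raise np.linalg.LinAlgError(
                f"training set covers {n_distinct} distinct directions; "
                f"need {C1.shape[0]}"
            )
        self.weights = B1 @ C1.T @ np.linalg.pinv(C1 @ C1.T)
        return self

    def invert(self, B2: np.ndarray) -> np.ndarray:
        """Channel response estimate C2_hat = (W'W)^+ W' B2 (channels x trials)."""
        if self.weights is None:
            raise RuntimeError("fit before invert")
        W = self.weights
        if np.linalg.matrix_rank(W) < W.shape[1] - 1:
            raise np.linalg.LinAlgError(
                "weight matrix rank too low to invert: need more neurons"
            )
        return np.linalg.pinv(W.T @ W) @ (W.T @ B2)


def iem_fit(B1, C1) -> InvertedEncodingModel:
    return InvertedEncodingModel().fit(B1, C1)


def iem_invert(model: InvertedEncodingModel, B2) -> np.ndarray:
    return model.invert(B2)


def align_ctf(C2: np.ndarray, dir_idx: np.ndarray) -> np.ndarray:
    """Zero-center channel responses on each trial's presented direction.

    Returns trials x 8 in ALIGNED_OFFSETS order (-180..135).
    """
    C2 = np.asarray(C2, float)
    dir_idx = np.atleast_1d(dir_idx)
    rolled = np.empty((dir_idx.size, 8))
    roll = np.arange(8)
    for t, d in enumerate(dir_idx):
        rolled[t] = C2[(d + roll) % 8, t]  # offsets 0,45,...,315
    order = np.array([4, 5, 6, 7, 0, 1, 2, 3])
    return rolled[:, order]


def ctf_slope(ctf: np.ndarray) -> float | np.ndarray:
    """Slope of a zero-centered CTF (ALIGNED_OFFSETS order).

    The three positive offsets are reflected onto their negatives (duplicated
    points, per the eight-point regression convention) and an OLS line with
    intercept is fitted from -180 to 0.
    """
    ctf = np.asarray(ctf, float)
    return ctf @ _CTF_W


@dataclasses.dataclass
class DecodingSeries:
    times: np.ndarray
    series: pd.DataFrame  # one column per condition/scheme
    decoder: str


def _loo_iem_slopes(B: np.ndarray, C: np.ndarray, dir_idx: np.ndarray) -> float:
    """Leave-one-trial-out CTF slope at one time bin (mean aligned CTF)."""
    M = C @ C.T
    N = B @ C.T
    ctfs = np.empty((B.shape[1], 8))
    for t in range(B.shape[1]):
        c = C[:, t]
        b = B[:, t]
        Mt = M - np.outer(c, c)
        Nt = N - np.outer(b, c)
        W = Nt @ np.linalg.pinv(Mt)
        ctfs[t] = np.linalg.pinv(W.T @ W) @ (W.T @ b)
    aligned = align_ctf(ctfs.T, dir_idx)
    return float(ctf_slope(aligned.mean(axis=0)))


def iem_timecourse(
    traces,
    trials: pd.DataFrame,
    frame_rate: float,
    decimate: int = 1,
    t_start: float = -0.5,
    t_stop: float = 4.0,
    directions=DIRECTION_SET,
) -> DecodingSeries:
    """Time-resolved CTF slope: LOO CV on homogeneous trials; heterogeneous
    trials tested with the hom-trained weights at the same time bin."""
    dirs = np.asarray(directions, float)
    hom = trials[trials["variance_condition"] == "hom"]
    het = trials[trials["variance_condition"] == "het"]
    Bh, times = epoch_tensor(traces, hom, frame_rate, t_start, t_stop, decimate)
    hom_idx = np.searchsorted(dirs, hom["mean_direction"].to_numpy())
    C_hom = make_basis(hom["mean_direction"].to_numpy())
    slopes_hom = np.empty(times.size)
    slopes_het = np.full(times.size, np.nan)
    if len(het):
        Bt, _ = epoch_tensor(traces, het, frame_rate, t_start, t_stop, decimate)
        het_idx = np.searchsorted(dirs, het["mean_direction"].to_numpy())
    model = InvertedEncodingModel()
    for k in range(times.size):
        Bk = Bh[:, :, k].T  # neurons x trials
        slopes_hom[k] = _loo_iem_slopes(Bk, C_hom, hom_idx)
        if len(het):
            model.fit(Bk, C_hom)
            C2 = model.invert(Bt[:, :, k].T)
            slopes_het[k] = float(ctf_slope(align_ctf(C2, het_idx).mean(axis=0)))
    df = pd.DataFrame({"time": times, "slope_hom": slopes_hom, "slope_het": slopes_het})
    return DecodingSeries(times=times, series=df, decoder="iem")


def _svm() -> LinearSVC:
    return LinearSVC(C=1.0, class_weight="balanced", dual="auto", max_iter=20000)


def _loo_accuracy(X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out accuracy of the linear SVM."""
    n = len(y)
    correct = 0
    idx = np.arange(n)
    for t in range(n):
        keep = idx != t
        if np.unique(y[keep]).size < 2:
            raise ValueError("single-class training set in LOO fold")
        clf = _svm().fit(X[keep], y[keep])
        correct += int(clf.predict(X[t : t + 1])[0] == y[t])
    return correct / n


def svm_condition_timecourse(
    traces,
    trials: pd.DataFrame,
    frame_rate: float,
    label: str = "variance",
    decimate: int = 1,
    t_start: float = -0.5,
    t_stop: float = 4.0,
) -> DecodingSeries:
    """Per-bin linear-SVM accuracy for variance (hom vs het, LOO over all
    trials) or category (left vs right: LOO on hom, hom-trained transfer to
    het)."""
    if label == "variance":
        y = (trials["variance_condition"] == "het").to_numpy()
        if np.unique(y).size < 2:
            raise ValueError("variance decoding needs both hom and het trials")
        T, times = epoch_tensor(traces, trials, frame_rate, t_start, t_stop, decimate)
        acc = np.array([_loo_accuracy(T[:, :, k], y) for k in range(times.size)])
        df = pd.DataFrame({"time": times, "accuracy": acc})
    elif label == "category":
        hom = trials[trials["variance_condition"] == "hom"]
        het = trials[trials["variance_condition"] == "het"]
        y_hom = (hom["category"] == "right").to_numpy()
        if np.unique(y_hom).size < 2:
            raise ValueError("category decoding needs both categories")
        Th, times = epoch_tensor(traces, hom, frame_rate, t_start, t_stop, decimate)
        acc_hom = np.empty(times.size)
        acc_het = np.full(times.size, np.nan)
        if len(het):
            Tt, _ = epoch_tensor(traces, het, frame_rate, t_start, t_stop, decimate)
            y_het = (het["category"] == "right").to_numpy()
        for k in range(times.size):
            acc_hom[k] = _loo_accuracy(Th[:, :, k], y_hom)
            if len(het):
                clf = _svm().fit(Th[:, :, k], y_hom)
                acc_het[k] = float((clf.predict(Tt[:, :, k]) == y_het).mean())
        df = pd.DataFrame({"time": times, "accuracy_hom": acc_hom, "accuracy_het": acc_het})
    else:
        raise ValueError("label must be 'variance' or 'category'")
    return DecodingSeries(times=df["time"].to_numpy(), series=df, decoder=f"svm_{label}")


#: direction indices (0-based into the sorted DIRECTION_SET) of the four
#: 90-deg-apart pairs on each side of the category boundary
WCD_PAIRS = ((0, 6), (1, 7), (2, 4), (3, 5))  # same category
BCD_PAIRS = ((0, 2), (1, 3), (4, 6), (5, 7))  # across the boundary


def _pair_cv_accuracy(
    Xh: np.ndarray,
    yh: np.ndarray,
    Xt: np.ndarray | None,
    yt: np.ndarray | None,
    n_repeats: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Repeated stratified 5-fold CV on hom; transfer of each fold's model to het."""
    accs_h, accs_t = [], []
    for _ in range(n_repeats):
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=int(rng.integers(2**31)))
        for tr_idx, te_idx in skf.split(Xh, yh):
            clf = _svm().fit(Xh[tr_idx], yh[tr_idx])
            accs_h.append((clf.predict(Xh[te_idx]) == yh[te_idx]).mean())
            if Xt is not None and len(yt):
                accs_t.append((clf.predict(Xt) == yt).mean())
    return float(np.mean(accs_h)), float(np.mean(accs_t)) if accs_t else np.nan


def wcd_bcd(
    traces,
    trials: pd.DataFrame,
    frame_rate: float,
    n_repeats: int = 100,
    rng: np.random.Generator | None = None,
    window: tuple[float, float] = (0.0, 4.0),
    directions=DIRECTION_SET,
) -> pd.DataFrame:
    """Within- vs between-category discrimination over a time window.

    For each of the four WCD and four BCD direction pairs, a linear SVM is
    trained on homogeneous trials (repeated stratified 5-fold CV) and the
    hom-trained fold models are applied to heterogeneous trials of the same
    pair.  Accuracies are averaged over pairs; rows report hom and het
    accuracies and the BCD - WCD difference.
    """
    rng = rng or np.random.default_rng()
    dirs = np.asarray(directions, float)
    hom = trials[trials["variance_condition"] == "hom"]
    het = trials[trials["variance_condition"] == "het"]
    from .epochs import trial_window_mean

    Xh_all = trial_window_mean(traces, hom, frame_rate, *window)
    Xt_all = trial_window_mean(traces, het, frame_rate, *window) if len(het) else None
    out = {}
    for name, pairs in (("wcd", WCD_PAIRS), ("bcd", BCD_PAIRS)):
        h_accs, t_accs = [], []
        for i, j in pairs:
            da, db = dirs[i], dirs[j]
            mh = hom["mean_direction"].isin([da, db]).to_numpy()
            if mh.sum() < 10:
                raise ValueError(f"pair ({da}, {db}): too few hom trials for 5-fold CV")
            yh = (hom.loc[mh, "mean_direction"] == da).to_numpy()
            Xt, yt = None, None
            if Xt_all is not None:
                mt = het["mean_direction"].isin([da, db]).to_numpy()
                Xt = Xt_all[mt]
                yt = (het.loc[mt, "mean_direction"] == da).to_numpy()
            ah, at = _pair_cv_accuracy(Xh_all[mh], yh, Xt, yt, n_repeats, rng)
            h_accs.append(ah)
            t_accs.append(at)
        out[f"{name}_hom"] = float(np.mean(h_accs))
        out[f"{name}_het"] = float(np.nanmean(t_accs))
    out["diff_hom"] = out["bcd_hom"] - out["wcd_hom"]
    out["diff_het"] = out["bcd_het"] - out["wcd_het"]
    return pd.DataFrame([out])


@dataclasses.dataclass
class TGMatrix:
    times: np.ndarray
    matrix: np.ndarray  # train bins x test bins
    decoder: str


def temporal_generalization(
    traces,
    trials: pd.DataFrame,
    frame_rate: float,
    decoder: str = "iem",
    decimate: int = 1,
    t_start: float = -0.5,
    t_stop: float = 4.0,
    n_splits: int = 5,
    rng: np.random.Generator | None = None,
    directions=DIRECTION_SET,
) -> TGMatrix:
    """Train at bin t, test at bin t': CTF slope (iem) or accuracy maps.

    ``iem`` and ``svm_category`` train on all homogeneous trials and test on
    heterogeneous trials (disjoint sets, so the diagonal matches the
    time-resolved transfer series).  ``svm_variance`` uses stratified random
    splits averaged over ``n_splits`` partitions.
    """
    rng = rng or np.random.default_rng()
    dirs = np.asarray(directions, float)
    hom = trials[trials["variance_condition"] == "hom"]
    het = trials[trials["variance_condition"] == "het"]
    if decoder in ("iem", "svm_category") and len(het) == 0:
        raise ValueError(f"{decoder} temporal generalization needs het test trials")
    if decoder == "iem":
        Bh, times = epoch_tensor(traces, hom, frame_rate, t_start, t_stop, decimate)
        Bt, _ = epoch_tensor(traces, het, frame_rate, t_start, t_stop, decimate)
        het_idx = np.searchsorted(dirs, het["mean_direction"].to_numpy())
        C_hom = make_basis(hom["mean_direction"].to_numpy())
        n = times.size
        mat = np.empty((n, n))
        model = InvertedEncodingModel()
        for t in range(n):
            model.fit(Bh[:, :, t].T, C_hom)
            for u in range(n):
                C2 = model.invert(Bt[:, :, u].T)
                mat[t, u] = float(ctf_slope(align_ctf(C2, het_idx).mean(axis=0)))
    elif decoder == "svm_category":
        Th, times = epoch_tensor(traces, hom, frame_rate, t_start, t_stop, decimate)
        Tt, _ = epoch_tensor(traces, het, frame_rate, t_start, t_stop, decimate)
        yh = (hom["category"] == "right").to_numpy()
        yt = (het["category"] == "right").to_numpy()
        n = times.size
        mat = np.empty((n, n))
        for t in range(n):
            clf = _svm().fit(Th[:, :, t], yh)
            for u in range(n):
                mat[t, u] = float((clf.predict(Tt[:, :, u]) == yt).mean())
    elif decoder == "svm_variance":
        T, times = epoch_tensor(traces, trials, frame_rate, t_start, t_stop, decimate)
        y = (trials["variance_condition"] == "het").to_numpy()
        n = times.size
        mat = np.zeros((n, n))
        skf = StratifiedKFold(
            n_splits=n_splits, shuffle=True, random_state=int(rng.integers(2**31))
        )
        for tr_idx, te_idx in skf.split(T[:, :, 0], y):
            for t in range(n):
                clf = _svm().fit(T[tr_idx][:, :, t], y[tr_idx])
                for u in range(n):
                    mat[t, u] += (clf.predict(T[te_idx][:, :, u]) == y[te_idx]).mean()
        mat /= n_splits
    else:
        raise ValueError(f"unknown decoder {decoder!r}")
    return TGMatrix(times=times, matrix=mat, decoder=decoder)
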