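"""Categorical bias of the population representation.

The time-averaged PRC for each presented direction is re-anchored to absolute
direction and fitted with a wrapped normal

    f(theta; mu, sigma) = sum_{k=-K..K} exp(-(theta - mu + 360 k)^2 / (2 sigma^2))

scaled by an amplitude and shifted by an additive offset (PRCs carry arbitrary
scale and baseline).  The truncation K = 3 is negligible for sigma <= 90 deg.
The signed bias is the wrapped difference mu - theta_sample, positive when the
fitted peak is displaced toward the nearest horizontal category center (0 deg
for the right category, 180 deg for the left) and negative when displaced
toward the vertical boundary.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import ttest_1samp, ttest_rel

from ._angles import nearest_category_center, wrap180, wrap360
from .prc import PRCTensor
from .stats import bh_fdr

TRUNCATION_K = 3


def wrapped_normal_density(theta, mu: float, sigma: float, K: int = TRUNCATION_K):
    """Unnormalized wrapped normal: peak value ~1 at theta == mu."""
    theta = np.asarray(theta, float)
    out = np.zeros_like(theta)
    for k in range(-K, K + 1):
        out = out + np.exp(-((theta - mu + 360.0 * k) ** 2) / (2.0 * sigma**2))
    return out


class WrappedNormalModel:
    """Nonlinear least-squares fit of amplitude * f(theta; mu, sigma) + offset.

    ``theta`` are absolute directions (degrees), ``y`` the PRC values there.
    """

    def __init__(self, theta, y):
        self.theta = wrap360(np.asarray(theta, float))
        self.y = np.asarray(y, float)
        if np.unique(self.theta).size < 5:
            raise ValueError("need >= 5 distinct direction samples")

    def fit(self) -> "WrappedNormalResults":
        y = self.y
        flat = not np.isfinite(y).all() or np.ptp(y) < 1e-12
        if flat:
            return WrappedNormalResults(self, np.nan, np.nan, np.nan, np.nan, False)
        mu0 = float(self.theta[np.argmax(y)])
        p0 = [mu0, 40.0, float(np.ptp(y)), float(y.min())]

        def model(theta, mu, sigma, amp, off):
            return amp * wrapped_normal_density(theta, mu, sigma) + off

        try:
            popt, _ = optimize.curve_fit(
                model,
                self.theta,
                y,
                p0=p0,
                bounds=([mu0 - 180.0, 3.0, 0.0, -np.inf], [mu0 + 180.0, 180.0, np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            return WrappedNormalResults(self, np.nan, np.nan, np.nan, np.nan, False)
        mu, sigma, amp, off = (float(v) for v in popt)
        return WrappedNormalResults(self, wrap360(mu).item(), sigma, amp, off, True)


@dataclasses.dataclass
class WrappedNormalResults:
    model: WrappedNormalModel
    mu: float  # fitted peak, degrees in [0, 360)
    sigma_w: float  # tuning width, degrees
    amplitude: float
    offset: float
    converged: bool

    def predict(self, theta):
        return self.amplitude * wrapped_normal_density(theta, self.mu, self.sigma_w) + self.offset

    def summary(self) -> str:
        if not self.converged:
            return "Wrapped-normal fit: did not converge (flat or degenerate input)"
        return (
            "Wrapped-normal fit\n"
            f"  mu (peak)  {self.mu:7.2f} deg\n"
            f"  sigma_w    {self.sigma_w:7.2f} deg\n"
            f"  amplitude  {self.amplitude:7.3f}\n"
            f"  offset     {self.offset:7.3f}"
        )


def fit_wrapped_normal(theta, y) -> WrappedNormalResults:
    """Functional wrapper around WrappedNormalModel(...).fit()."""
    return WrappedNormalModel(theta, y).fit()


def signed_bias(mu: float, theta_sample: float) -> float:
    """Wrapped difference mu - theta_sample, sign-adjusted toward the center.

    Positive = fitted peak displaced toward the nearest horizontal category
    center; negative = toward the vertical boundary.  theta_sample on the
    boundary itself has no defined sign.
    """
    theta_sample = float(wrap360(theta_sample))
    if theta_sample in (90.0, 270.0):
        raise ValueError("theta_sample on the category boundary: sign undefined")
    raw = float(wrap180(mu - theta_sample))
    center = nearest_category_center(theta_sample)
    toward = float(wrap180(center - theta_sample))
    return float(np.sign(raw * toward) * abs(raw)) if raw != 0 else 0.0


def estimate_session_bias(prc: PRCTensor, directions=None) -> pd.DataFrame:
    """Per presented direction: wrapped-normal peak and signed bias.

    Averages the per-direction PRC over the 0-4 s stimulus window, re-anchors
    offsets to absolute direction, fits, and signs the peak displacement.
    Non-converged fits are flagged and carry NaN bias.
    """
    if directions is None:
        from ._angles import DIRECTION_SET

        directions = DIRECTION_SET
    stim = prc.times >= 0
    rows = []
    for d_idx, theta_s in enumerate(directions):
        y = prc.by_direction[d_idx][:, stim].mean(axis=1)
        theta = wrap360(theta_s + prc.offsets)
        fit = fit_wrapped_normal(theta, y) if np.isfinite(y).all() else None
        ok = fit is not None and fit.converged
        rows.append(
            {
                "theta_sample": float(theta_s),
                "mu": fit.mu if ok else np.nan,
                "raw_difference": float(wrap180(fit.mu - theta_s)) if ok else np.nan,
                "signed_bias": signed_bias(fit.mu, theta_s) if ok else np.nan,
                "sigma_w": fit.sigma_w if ok else np.nan,
                "converged": ok,
            }
        )
    return pd.DataFrame(rows)


def tukey_exclude(values: np.ndarray, iqr_k: float = 1.5) -> np.ndarray:
    """Boolean mask of values kept by the Tukey fence (quartiles +- k IQR)."""
    v = np.asarray(values, float)
    q1, q3 = np.percentile(v[np.isfinite(v)], [25, 75])
    iqr = q3 - q1
    return (v >= q1 - iqr_k * iqr) & (v <= q3 + iqr_k * iqr) & np.isfinite(v)


def bias_summary(
    biases_by_condition: dict, iqr_k: float = 1.5, alpha: float = 0.05,
    paired_with: dict | None = None,
) -> pd.DataFrame:
    """Group-level bias table with outlier exclusion and FDR-corrected tests.

    ``biases_by_condition`` maps condition name -> per-subject mean bias array
    (>= 3 subjects).  Each condition gets a Tukey-fence exclusion and a
    one-sample t-test vs 0; with ``paired_with`` (same keys, e.g. passive
    sessions) a paired t-test is added.  BH-FDR corrects across conditions.
    """
    rows = []
    for cond, vals in biases_by_condition.items():
        vals = np.asarray(vals, float)
        keep = tukey_exclude(vals, iqr_k)
        kept = vals[keep]
        if kept.size < 3:
            rows.append(
                {"condition": cond, "n": int(kept.size), "mean_bias": np.nan,
                 "t": np.nan, "p": np.nan, "n_excluded": int((~keep).sum()),
                 "dropped": True}
            )
            continue
        t, p = ttest_1samp(kept, 0.0)
        row = {
            "condition": cond, "n": int(kept.size), "mean_bias": float(kept.mean()),
            "t": float(t), "p": float(p), "n_excluded": int((~keep).sum()),
            "dropped": False,
        }
        if paired_with is not None and cond in paired_with:
            other = np.asarray(paired_with[cond], float)
            tp, pp = ttest_rel(vals, other)
            row["t_paired"], row["p_paired"] = float(tp), float(pp)
        rows.append(row)
    df = pd.DataFrame(rows)
    ok = df["p"].notna()
    p_adj = np.full(len(df), np.nan)
    sig = np.zeros(len(df), dtype=bool)
    if ok.any():
        rej, adj = bh_fdr(df.loc[ok, "p"].to_numpy(), alpha=alpha)
        p_adj[ok.to_numpy()] = adj
        sig[ok.to_numpy()] = rej
    df["p_fdr"] = p_adj
    df["significant"] = sig
    return df
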