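"""Psychometric analysis of categorical choices.

The proportion of "right" choices as a function of the mean motion direction
is fitted with a cumulative normal by binomial maximum likelihood.  The
circle is first folded onto [-90, +90] degrees of signed distance from the
vertical category boundary (positive toward 0deg), which makes the monotone
cumulative-normal model well posed.  The psychometric slope is reported as
1/sigma.  Sensitivity is also summarized as d' = sqrt(2) * Z(p_correct),
the standard two-alternative forced-choice relation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

from ._angles import EASY_DIRECTIONS, signed_distance_from_boundary

SIGMA_MIN = 0.5  # degrees; reached under perfect separation
SIGMA_MAX = 1e4  # degrees; reached for flat (chance) data


class PsychometricModel:
    """Binomial cumulative-normal model of P(right) vs signed direction.

    Parameters
    ----------
    signed_distance : array of stimulus levels, degrees from the boundary
        (positive = right category).
    n_right, n_total : per-level counts.
    lapse : fixed lapse rate (default 0; the fitted parameters are mu, sigma).
    """

    def __init__(self, signed_distance, n_right, n_total, lapse: float = 0.0):
        self.x = np.asarray(signed_distance, float)
        self.k = np.asarray(n_right, float)
        self.n = np.asarray(n_total, float)
        if not (self.x.shape == self.k.shape == self.n.shape):
            raise ValueError("signed_distance, n_right, n_total must share shape")
        if np.unique(self.x).size < 4:
            raise ValueError("need >= 4 distinct stimulus levels")
        if np.any(self.n < 1):
            raise ValueError("every level needs at least one trial")
        self.lapse = float(lapse)

    @classmethod
    def from_trials(cls, trials: pd.DataFrame, lapse: float = 0.0) -> "PsychometricModel":
        """Aggregate a trial table (choice in {left, right}) by direction."""
        t = trials[trials["choice"].isin(["left", "right"])].copy()
        t["x"] = signed_distance_from_boundary(t["mean_direction"].to_numpy())
        g = t.groupby("x")["choice"].agg(
            n_right=lambda c: int((c == "right").sum()), n_total="size"
        )
        return cls(g.index.to_numpy(), g["n_right"].to_numpy(), g["n_total"].to_numpy(), lapse)

    def _loglike(self, mu: float, sigma: float) -> float:
        p = (1.0 - self.lapse) * norm.cdf((self.x - mu) / sigma) + self.lapse / 2.0
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return float(np.sum(self.k * np.log(p) + (self.n - self.k) * np.log(1.0 - p)))

    def fit(self) -> "PsychometricResults":
        span = self.x.max() - self.x.min()
        starts = [
            (0.0, max(span / 4.0, 2 * SIGMA_MIN)),
            (float(np.median(self.x)), span),
            (0.0, 5 * SIGMA_MIN),
        ]
        best = None
        for mu0, sig0 in starts:
            res = optimize.minimize(
                lambda th: -self._loglike(th[0], th[1]),
                x0=[mu0, sig0],
                method="L-BFGS-B",
                bounds=[(self.x.min() - span, self.x.max() + span), (SIGMA_MIN, SIGMA_MAX)],
            )
            if best is None or res.fun < best.fun:
                best = res
        mu, sigma = float(best.x[0]), float(best.x[1])
        return PsychometricResults(
            model=self,
            mu=mu,
            sigma=sigma,
            log_likelihood=-float(best.fun),
            n_trials=int(self.n.sum()),
            at_lower_bound=bool(np.isclose(sigma, SIGMA_MIN, rtol=1e-3)),
            at_upper_bound=bool(sigma > 0.5 * SIGMA_MAX),
        )


@dataclasses.dataclass
class PsychometricResults:
    """Fitted cumulative-normal parameters; slope is 1/sigma by construction."""

    model: PsychometricModel
    mu: float  # 50% point, degrees
    sigma: float  # degrees
    log_likelihood: float
    n_trials: int
    at_lower_bound: bool  # perfect separation: sigma pinned at its floor
    at_upper_bound: bool  # flat data: sigma at its ceiling, slope ~ 0

    @property
    def slope(self) -> float:
        return 1.0 / self.sigma

    def predict(self, signed_distance) -> np.ndarray:
        x = np.asarray(signed_distance, float)
        m = self.model
        return (1.0 - m.lapse) * norm.cdf((x - self.mu) / self.sigma) + m.lapse / 2.0

    def summary(self) -> str:
        flag = (
            " [perfect separation]"
            if self.at_lower_bound
            else (" [flat data]" if self.at_upper_bound else "")
        )
        return (
            "Cumulative-normal psychometric fit\n"
            f"  n_trials        {self.n_trials}\n"
            f"  mu (50% point)  {self.mu:8.2f} deg\n"
            f"  sigma           {self.sigma:8.2f} deg{flag}\n"
            f"  slope (1/sigma) {self.slope:8.4f} per deg\n"
            f"  log-likelihood  {self.log_likelihood:8.2f}"
        )


def fit_cumulative_normal(
    prop_right_by_direction: dict, n_by_direction: dict, lapse: float = 0.0
) -> PsychometricResults:
    """Convenience wrapper: directions (degrees) -> proportion right, counts."""
    dirs = sorted(prop_right_by_direction)
    x = signed_distance_from_boundary(np.array(dirs, float))
    n = np.array([n_by_direction[d] for d in dirs], float)
    k = np.round(np.array([prop_right_by_direction[d] for d in dirs]) * n)
    return PsychometricModel(x, k, n, lapse=lapse).fit()


def dprime(p: float, n_trials: int | None = None) -> float:
    """d' = sqrt(2) * Z(p) for 2AFC proportion correct p.

    Proportions of exactly 0 or 1 are clipped to 1/(2N) and 1 - 1/(2N); the
    trial count is then required.
    """
    if p <= 0.0 or p >= 1.0:
        if n_trials is None:
            raise ValueError("p in {0, 1} requires n_trials for the 1/(2N) clipping rule")
        lo = 1.0 / (2.0 * n_trials)
        p = min(max(p, lo), 1.0 - lo)
    return float(np.sqrt(2.0) * norm.ppf(p))


def summarize_behavior(trials: pd.DataFrame) -> dict:
    """Per-direction choice proportions and per condition x difficulty d'.

    Returns a dict with ``per_direction`` (DataFrame: mean_direction,
    prop_right, n) and ``dprime_table`` (DataFrame: condition, difficulty,
    prop_correct, d_prime, n) shaped for external mixed-model fitting.
    Empty cells are omitted.
    """
    t = trials[trials["choice"].isin(["left", "right"])].copy()
    per_dir = (
        t.groupby("mean_direction")
        .agg(prop_right=("choice", lambda c: float((c == "right").mean())), n=("choice", "size"))
        .reset_index()
    )
    t["difficulty"] = np.where(
        t["mean_direction"].isin(list(EASY_DIRECTIONS)), "easy", "hard"
    )
    rows = []
    for (cond, diff), g in t.groupby(["variance_condition", "difficulty"]):
        n = len(g)
        if n == 0:  # pragma: no cover - groupby never yields empty groups
            continue
        p = float(g["correct"].mean())
        rows.append(
            {
                "condition": cond,
                "difficulty": diff,
                "prop_correct": p,
                "d_prime": dprime(p, n_trials=n),
                "n": n,
            }
        )
    return {"per_direction": per_dir, "dprime_table": pd.DataFrame(rows)}
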