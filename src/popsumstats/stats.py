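"""Shared inference machinery: cluster-mass permutation tests and BH-FDR.

The cluster test corrects across time bins (1-D) or train x test bin pairs
(2-D, 4-connectivity): bin-wise t-tests at an uncorrected cluster-forming
threshold define contiguous supra-threshold clusters, each summarized by its
mass (sum of t values); the null distribution of the maximum cluster mass is
built by sign-flipping subjects (one-sample / paired) or exchanging condition
labels within subject (two-sample), and cluster p-values use the add-one rule
p = (1 + #null >= observed) / (1 + n_perm).  Positive and negative clusters
are formed separately and compared against the two-sided max-|mass| null.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclasses.dataclass
class Cluster:
    indices: np.ndarray  # bin indices (1-D) or flat indices into the map (2-D)
    extent: int
    mass: float
    p_value: float


@dataclasses.dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    significant: np.ndarray  # boolean mask over bins / bin pairs
    t_values: np.ndarray
    n_perm: int
    alpha: float
    kind: str
    statistic: str  # 'mass' or 'extent'

    @property
    def any_significant(self) -> bool:
        return bool(self.significant.any())


def _one_sample_t(data: np.ndarray, mu0: float = 0.0):
    """Vectorized one-sample t over axis 0; NaN-safe for zero variance."""
    n = data.shape[0]
    m = data.mean(axis=0) - mu0
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    return t, n - 1


def _clusters_from_t(t: np.ndarray, thresh: float, statistic: str):
    """Positive and negative supra-threshold clusters with their stats."""
    out = []
    finite = np.nan_to_num(t, nan=0.0)
    for sign in (1.0, -1.0):
        mask = sign * finite > thresh
        if t.ndim == 1:
            labels, n_lab = ndimage.label(mask)
        else:
            labels, n_lab = ndimage.label(mask, structure=ndimage.generate_binary_structure(2, 1))
        for lab in range(1, n_lab + 1):
            idx = np.flatnonzero(labels.ravel() == lab)
            mass = float(np.abs(finite.ravel()[idx]).sum())
            stat = mass if statistic == "mass" else float(idx.size)
            out.append((idx, int(idx.size), mass, stat))
    return out


def _max_cluster_stat(t: np.ndarray, thresh: float, statistic: str) -> float:
    cl = _clusters_from_t(t, thresh, statistic)
    return max((c[3] for c in cl), default=0.0)


def _cluster_perm(
    data: np.ndarray,
    kind: str,
    mu0: float,
    n_perm: int,
    alpha: float,
    cluster_alpha: float,
    statistic: str,
    rng: np.random.Generator | None,
    data_b: np.ndarray | None = None,
) -> ClusterTestResult:
    if n_perm < 100:
        raise ValueError("n_perm < 100: permutation p-values too coarse")
    rng = rng or np.random.default_rng()
    data = np.asarray(data, float)
    if kind in ("one_sample", "paired"):
        if kind == "paired":
            if data_b is None:
                raise ValueError("paired test needs two data arrays")
            data = data - np.asarray(data_b, float)
            mu0 = 0.0
        n_sub = data.shape[0]
        if n_sub < 3:
            raise ValueError("need >= 3 subjects")
        t_obs, df = _one_sample_t(data, mu0)
        thresh = sps.t.ppf(1 - cluster_alpha / 2, df)
        centered = data - mu0
        # sign flips leave per-subject squares unchanged: vectorized t per perm
        sumsq = (centered**2).sum(axis=0)
        null = np.empty(n_perm)
        shape = centered.shape[1:]
        flat = centered.reshape(n_sub, -1)
        for p in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=n_sub)
            m = (signs @ flat) / n_sub
            var = (sumsq.ravel() - n_sub * m**2) / (n_sub - 1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t_p = m / np.sqrt(var / n_sub)
            null[p] = _max_cluster_stat(t_p.reshape(shape), thresh, statistic)
    elif kind == "two_sample":
        if data_b is None:
            raise ValueError("two_sample test needs two data arrays")
        b = np.asarray(data_b, float)
        if data.shape[0] < 3 or b.shape[0] < 3:
            raise ValueError("need >= 3 subjects per group")
        na, nb = data.shape[0], b.shape[0]
        pooled = np.concatenate([data, b], axis=0)

        def welch_t(x, y):
            mx, my = x.mean(axis=0), y.mean(axis=0)
            vx = x.var(axis=0, ddof=1) / x.shape[0]
            vy = y.var(axis=0, ddof=1) / y.shape[0]
            with np.errstate(divide="ignore", invalid="ignore"):
                return (mx - my) / np.sqrt(vx + vy)

        t_obs = welch_t(data, b)
        df = min(na, nb) - 1  # conservative df for the forming threshold
        thresh = sps.t.ppf(1 - cluster_alpha / 2, df)
        null = np.empty(n_perm)
        for p in range(n_perm):
            perm = rng.permutation(na + nb)
            t_p = welch_t(pooled[perm[:na]], pooled[perm[na:]])
            null[p] = _max_cluster_stat(t_p, thresh, statistic)
    else:
        raise ValueError(f"unknown test kind {kind!r}")

    clusters = []
    sig = np.zeros(t_obs.shape, dtype=bool)
    for idx, extent, mass, stat in _clusters_from_t(t_obs, thresh, statistic):
        p_val = (1.0 + np.sum(null >= stat)) / (1.0 + n_perm)
        clusters.append(Cluster(indices=idx, extent=extent, mass=mass, p_value=p_val))
        if p_val <= alpha:
            sig.ravel()[idx] = True
    clusters.sort(key=lambda c: c.p_value)
    return ClusterTestResult(
        clusters=clusters,
        significant=sig,
        t_values=t_obs,
        n_perm=n_perm,
        alpha=alpha,
        kind=kind,
        statistic=statistic,
    )


def cluster_perm_1d(
    data: np.ndarray,
    kind: str = "one_sample",
    mu0: float = 0.0,
    n_perm: int = 5000,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    statistic: str = "mass",
    rng: np.random.Generator | None = None,
    data_b: np.ndarray | None = None,
) -> ClusterTestResult:
    """Cluster-mass permutation test over a subjects x bins time series."""
    data = np.atleast_2d(np.asarray(data, float))
    if data.ndim != 2:
        raise ValueError("1-D test expects subjects x bins")
    return _cluster_perm(data, kind, mu0, n_perm, alpha, cluster_alpha, statistic, rng, data_b)


def cluster_perm_2d(
    data: np.ndarray,
    kind: str = "one_sample",
    mu0: float = 0.0,
    n_perm: int = 5000,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    statistic: str = "mass",
    rng: np.random.Generator | None = None,
    data_b: np.ndarray | None = None,
) -> ClusterTestResult:
    """Same machinery on subjects x train-bins x test-bins maps (4-connectivity)."""
    data = np.asarray(data, float)
    if data.ndim != 3:
        raise ValueError("2-D test expects subjects x trainbins x testbins")
    return _cluster_perm(data, kind, mu0, n_perm, alpha, cluster_alpha, statistic, rng, data_b)


def bh_fdr(pvalues, alpha: float = 0.05):
    """Benjamini-Hochberg step-up: (significance mask, adjusted p-values)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def welch_ttest(a, b) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t-test (statistic, p)."""
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)
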