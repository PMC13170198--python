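"""Regression-based representational similarity analysis.

At each time bin, linear discriminant analysis classifiers decode every pair
of the 16 stimulus conditions (8 directions x {hom, het}) from pseudo-trials;
the pairwise accuracies form a 16 x 16 neural representational dissimilarity
matrix (RDM; higher accuracy = more dissimilar).  The neural RDM is regressed
on three z-scored model RDMs:

* mean      -- 1 minus the cosine similarity of channel-basis response
               vectors at the two directions (identical across variance
               pairings);
* variance  -- 0 if the two conditions share the variance condition, else 1;
* category  -- 0 if the two directions fall on the same side of the vertical
               boundary, else 1.

Pseudo-trials reduce trial-to-trial noise: trials of each condition are split
into four chunks (the CV folds), and each pseudo-trial averages a random 25%
of the trials within its chunk.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from ._angles import DIRECTION_SET, category_of
from .decoding import make_basis
from .epochs import epoch_tensor

#: condition ordering of RDM rows: 8 directions hom, then 8 directions het
CONDITION_ORDER = [(d, v) for v in ("hom", "het") for d in DIRECTION_SET]


@dataclasses.dataclass
class PseudoTrials:
    """Chunked pseudo-trial tensors per condition.

    ``data[c]`` has shape chunks x n_synth x neurons x bins for condition
    index c (CONDITION_ORDER).
    """

    data: list[np.ndarray]
    times: np.ndarray
    n_chunks: int


def pseudo_trials(
    traces,
    trials: pd.DataFrame,
    frame_rate: float,
    n_chunks: int = 4,
    frac: float = 0.25,
    n_synth: int = 500,
    rng: np.random.Generator | None = None,
    decimate: int = 1,
    t_start: float = -0.5,
    t_stop: float = 4.0,
) -> PseudoTrials:
    """Build pseudo-trials for each of the 16 conditions.

    Chunking is trial-order-stratified within condition (trial 0 -> chunk 0,
    trial 1 -> chunk 1, ...) to balance slow drift across folds.  Each
    pseudo-trial averages a random ceil(frac * chunk size) subset (>= 1 trial).
    """
    rng = rng or np.random.default_rng()
    tensor, times = epoch_tensor(traces, trials, frame_rate, t_start, t_stop, decimate)
    out = []
    for d, v in CONDITION_ORDER:
        mask = (
            (trials["variance_condition"] == v)
            & (trials["mean_direction"] == d)
        ).to_numpy()
        idx = np.flatnonzero(mask)
        if idx.size < n_chunks:
            raise ValueError(
                f"condition (direction={d}, {v}): {idx.size} trials < {n_chunks} chunks"
            )
        chunks = [idx[c::n_chunks] for c in range(n_chunks)]
        if min(len(c) for c in chunks) < 1:
            raise ValueError(f"condition (direction={d}, {v}): empty chunk")
        cond = np.empty((n_chunks, n_synth, tensor.shape[1], tensor.shape[2]))
        for c, ch in enumerate(chunks):
            k = max(1, int(np.ceil(frac * len(ch))))
            for s in range(n_synth):
                pick = rng.choice(ch, size=k, replace=False)
                cond[c, s] = tensor[pick].mean(axis=0)
        out.append(cond)
    return PseudoTrials(data=out, times=times, n_chunks=n_chunks)


def pairwise_rdm(pseudo: PseudoTrials, time_bin: int) -> np.ndarray:
    """16 x 16 pairwise LDA decoding-accuracy RDM at one time bin.

    Folds are the chunks: train on n_chunks - 1, test on the held-out chunk.
    Least-squares LDA with automatic (Ledoit-Wolf) covariance shrinkage keeps
    the discriminant defined when neurons approach the pseudo-trial count.
    Diagonal entries are NaN.
    """
    n_cond = len(pseudo.data)
    rdm = np.full((n_cond, n_cond), np.nan)
    n_chunks = pseudo.n_chunks
    X = [cond[:, :, :, time_bin] for cond in pseudo.data]  # chunks x synth x neurons
    for i in range(n_cond):
        for j in range(i + 1, n_cond):
            accs = []
            for fold in range(n_chunks):
                train_chunks = [c for c in range(n_chunks) if c != fold]
                Xtr = np.concatenate(
                    [X[i][train_chunks].reshape(-1, X[i].shape[2]),
                     X[j][train_chunks].reshape(-1, X[j].shape[2])]
                )
                ytr = np.repeat([0, 1], (n_chunks - 1) * X[i].shape[1])
                Xte = np.concatenate([X[i][fold], X[j][fold]])
                yte = np.repeat([0, 1], X[i].shape[1])
                clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
                clf.fit(Xtr, ytr)
                accs.append((clf.predict(Xte) == yte).mean())
            rdm[i, j] = rdm[j, i] = float(np.mean(accs))
    return rdm


def rdm_timecourse(pseudo: PseudoTrials) -> np.ndarray:
    """Stack of RDMs over all time bins: bins x 16 x 16."""
    return np.stack([pairwise_rdm(pseudo, k) for k in range(pseudo.times.size)])


def build_model_rdms(directions=DIRECTION_SET, power: int = 6) -> dict:
    """Mean / variance / category model RDMs over the 16-condition order.

    The mean RDM is 1 - cosine similarity of the channel-basis response
    vectors of the two directions; variance and category RDMs are binary.
    """
    dirs = [d for d, _ in CONDITION_ORDER]
    vars_ = [v for _, v in CONDITION_ORDER]
    B = make_basis(np.asarray(dirs, float), centers=directions, power=power)
    Bn = B / np.linalg.norm(B, axis=0, keepdims=True)
    cos = Bn.T @ Bn
    mean_rdm = 1.0 - cos
    span = mean_rdm.max()
    if span > 0:
        mean_rdm = mean_rdm / span  # scale entries onto [0, 1]
    n = len(CONDITION_ORDER)
    variance_rdm = np.array(
        [[0.0 if vars_[i] == vars_[j] else 1.0 for j in range(n)] for i in range(n)]
    )
    cats = category_of(np.asarray(dirs, float))
    category_rdm = np.array(
        [[0.0 if cats[i] == cats[j] else 1.0 for j in range(n)] for i in range(n)]
    )
    return {"mean": mean_rdm, "variance": variance_rdm, "category": category_rdm}


def _upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def regress_rdm(neural_rdms: np.ndarray, model_rdms: dict) -> pd.DataFrame:
    """OLS of the neural RDM on z-scored model RDMs, per time bin.

    Only upper-triangle off-diagonal entries enter the regression.  Returns a
    DataFrame with columns beta0, beta_mean, beta_variance, beta_category.
    """
    neural_rdms = np.asarray(neural_rdms, float)
    if neural_rdms.ndim == 2:
        neural_rdms = neural_rdms[None]
    names = ["mean", "variance", "category"]
    cols = []
    for name in names:
        v = _upper(model_rdms[name])
        sd = v.std()
        if sd == 0:
            raise ValueError(f"model RDM {name!r} is constant")
        cols.append((v - v.mean()) / sd)
    Xd = np.column_stack([np.ones_like(cols[0])] + cols)
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        raise ValueError("model RDMs are collinear")
    rows = []
    for k in range(neural_rdms.shape[0]):
        y = _upper(neural_rdms[k])
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        rows.append(
            {"beta0": beta[0], "beta_mean": beta[1],
             "beta_variance": beta[2], "beta_category": beta[3]}
        )
    return pd.DataFrame(rows)
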