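"""On-disk session schema: trial table as CSV, traces as HDF5, config as YAML.

A session directory contains::

    trials.csv   one row per trial (see TRIAL_COLUMNS)
    traces.h5    dataset ``dF_over_F`` [neurons x frames], attr ``frame_rate``
    config.yaml  generator / acquisition parameters (free-form mapping)

User-supplied data in the same schema is accepted by every analysis stage.
"""

from __future__ import annotations

import dataclasses
import pathlib

import h5py
import numpy as np
import pandas as pd
import yaml

TRIAL_COLUMNS = [
    "trial_id",
    "variance_condition",
    "het_range",
    "mean_direction",
    "category",
    "onset_frame",
    "choice",
    "correct",
]


@dataclasses.dataclass
class Session:
    """In-memory session: trial table + dF/F traces + acquisition metadata."""

    trials: pd.DataFrame
    traces: np.ndarray  # neurons x frames
    frame_rate: float
    config: dict = dataclasses.field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return int(self.traces.shape[0])

    @property
    def n_frames(self) -> int:
        return int(self.traces.shape[1])

    def validate(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        if self.trials["onset_frame"].max() >= self.n_frames:
            raise ValueError("trial onset beyond trace length")


def save_session(session: Session, out_dir) -> pathlib.Path:
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session.trials.to_csv(out / "trials.csv", index=False)
    with h5py.File(out / "traces.h5", "w") as f:
        ds = f.create_dataset("dF_over_F", data=np.asarray(session.traces, dtype=np.float64))
        ds.attrs["frame_rate"] = float(session.frame_rate)
    with open(out / "config.yaml", "w") as f:
        yaml.safe_dump(session.config, f)
    return out


def load_session(session_dir) -> Session:
    d = pathlib.Path(session_dir)
    trials = pd.read_csv(d / "trials.csv")
    with h5py.File(d / "traces.h5", "r") as f:
        traces = f["dF_over_F"][...]
        frame_rate = float(f["dF_over_F"].attrs["frame_rate"])
    cfg_path = d / "config.yaml"
    config = {}
    if cfg_path.exists():
        with open(cfg_path) as f:
            config = yaml.safe_load(f) or {}
    sess = Session(trials=trials, traces=traces, frame_rate=frame_rate, config=config)
    sess.validate()
    return sess
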