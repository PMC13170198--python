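"""Synthetic RDK sessions with known ground truth.

Emulates the study conditions of a head-fixed motion-categorization experiment:
eight mean directions (22.5deg-337.5deg, 45deg apart), homogeneous dot motion or
heterogeneous motion with dot directions drawn uniformly from a 90/180/270deg
range around the mean, direction-tuned neurons with variance-dependent gain,
GCaMP-like calcium dynamics (exponential decay, slow drift, Gaussian noise),
and choices following a cumulative-normal psychometric function around the
vertical category boundary.

Generative coding modes
-----------------------
``linear_sum``
    Each neuron's stimulus-period rate is the average of its tuning function
    over the individual dot directions (the null model in which a neuron merely
    pools local motion).  For cosine-like tuning this attenuates the tuning
    amplitude by sin(r/2)/(r/2) for a uniform direction range r.
``sharpened_mean``
    Tuning evaluated at the dots' circular mean, scaled by a per-range gain --
    a population that genuinely encodes the ensemble mean.
``untuned``
    Baseline only.
``category``
    Two rate levels keyed to the trial's left/right category.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy.stats import norm

from ._angles import (
    DIRECTION_SET,
    category_of,
    circmean_deg,
    nearest_category_center,
    signed_distance_from_boundary,
    wrap180,
    wrap360,
)
from .io import Session

CODING_MODES = ("linear_sum", "sharpened_mean", "untuned", "category")


@dataclasses.dataclass
class SessionConfig:
    """Stimulus / schedule parameters of one session."""

    direction_set: Sequence[float] = DIRECTION_SET
    het_range: float = 90.0  # degrees; 0 would mean a homogeneous-only session
    trials_per_direction: int = 20
    n_dots: int = 500
    frame_rate: float = 30.0  # Hz
    stim_duration: float = 4.0  # s
    pre_window: float = 2.0  # s before stimulus onset (inter-trial interval)
    post_window: float = 2.0  # s after stimulus offset (response + reward epoch)
    seed: int = 0

    def __post_init__(self):
        if self.trials_per_direction < 1:
            raise ValueError("trials_per_direction must be >= 1")
        if self.stim_duration <= 0:
            raise ValueError("stim_duration must be > 0")
        if self.het_range not in (0.0, 90.0, 180.0, 270.0):
            raise ValueError("het_range must be one of 0, 90, 180, 270 degrees")

    @property
    def pre_frames(self) -> int:
        return int(round(self.pre_window * self.frame_rate))

    @property
    def stim_frames(self) -> int:
        return int(round(self.stim_duration * self.frame_rate))

    @property
    def post_frames(self) -> int:
        return int(round(self.post_window * self.frame_rate))

    @property
    def frames_per_trial(self) -> int:
        return self.pre_frames + self.stim_frames + self.post_frames


@dataclasses.dataclass
class PopulationModel:
    """Generative parameters, one entry per neuron.

    ``gain_by_range`` maps a heterogeneity range (degrees) to a multiplicative
    gain applied in ``sharpened_mean`` mode; range 0 must map to 1.
    ``attraction_deg`` shifts the represented stimulus mean toward the nearest
    horizontal category center before tuning evaluation (sharpened_mean mode
    only) -- the generative analogue of a learned categorical bias.
    """

    preferred_direction: np.ndarray  # degrees
    amplitude: np.ndarray  # dF/F units
    width: np.ndarray  # tuning concentration kappa (dimensionless)
    baseline: np.ndarray  # dF/F units
    gain_by_range: Mapping[float, float] = dataclasses.field(
        default_factory=lambda: {0.0: 1.0, 90.0: 1.0, 180.0: 1.0, 270.0: 1.0}
    )
    coding_mode: str = "sharpened_mean"
    attraction_deg: float = 0.0

    def __post_init__(self):
        self.preferred_direction = np.atleast_1d(np.asarray(self.preferred_direction, float))
        n = self.preferred_direction.size
        self.amplitude = np.broadcast_to(np.asarray(self.amplitude, float), (n,)).copy()
        self.width = np.broadcast_to(np.asarray(self.width, float), (n,)).copy()
        self.baseline = np.broadcast_to(np.asarray(self.baseline, float), (n,)).copy()
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be nonnegative")
        if abs(self.gain_by_range.get(0.0, 1.0) - 1.0) > 1e-12:
            raise ValueError("gain_by_range must map range 0 to gain 1")
        if self.coding_mode not in CODING_MODES:
            raise ValueError(f"unknown coding_mode {self.coding_mode!r}")

    @property
    def n_neurons(self) -> int:
        return self.preferred_direction.size

    def tuning(self, theta, neuron=None):
        """Von-Mises-shaped tuning bump exp(kappa (cos(d) - 1)), peak value 1."""
        theta = np.atleast_1d(np.asarray(theta, float))
        pref = self.preferred_direction if neuron is None else self.preferred_direction[neuron]
        kappa = self.width if neuron is None else self.width[neuron]
        delta = np.deg2rad(theta[..., None] - np.atleast_1d(pref))
        out = np.exp(np.atleast_1d(kappa) * (np.cos(delta) - 1.0))
        return out


def make_population(
    n_neurons: int,
    rng: np.random.Generator,
    coding_mode: str = "sharpened_mean",
    amplitude: float = 1.0,
    width: float = 2.0,
    baseline: float = 0.1,
    gain_by_range: Mapping[float, float] | None = None,
    attraction_deg: float = 0.0,
    jitter_pref: float = 0.0,
    amplitude_cv: float = 0.0,
) -> PopulationModel:
    """Population with preferred directions tiling the circle uniformly.

    Preferred directions are assigned by cycling through the eight stimulus
    directions (plus optional jitter) so every direction bin is occupied.
    ``amplitude_cv`` draws per-neuron amplitudes from a lognormal with that
    coefficient of variation, mimicking response-strength heterogeneity.
    """
    prefs = np.array([DIRECTION_SET[i % 8] for i in range(n_neurons)], float)
    if jitter_pref > 0:
        prefs = wrap360(prefs + rng.uniform(-jitter_pref, jitter_pref, n_neurons))
    if gain_by_range is None:
        gain_by_range = {0.0: 1.0, 90.0: 1.0, 180.0: 0.85, 270.0: 0.6}
    amps = np.full(n_neurons, float(amplitude))
    if amplitude_cv > 0:
        sig = np.sqrt(np.log(1.0 + amplitude_cv**2))
        amps = amps * rng.lognormal(-(sig**2) / 2.0, sig, n_neurons)
    return PopulationModel(
        preferred_direction=prefs,
        amplitude=amps,
        width=np.full(n_neurons, width),
        baseline=np.full(n_neurons, baseline),
        gain_by_range=dict(gain_by_range),
        coding_mode=coding_mode,
        attraction_deg=attraction_deg,
    )


@dataclasses.dataclass
class CalciumParams:
    """GCaMP6f-like trace dynamics."""

    decay_tau: float = 0.6  # s
    noise_sd: float = 0.05  # dF/F
    drift_amplitude: float = 0.05  # dF/F
    drift_period: float = 120.0  # s

    def __post_init__(self):
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclasses.dataclass
class PsychParams:
    """Cumulative-normal psychometric model of the categorical choice."""

    sigma: float = 22.5  # degrees
    lapse: float = 0.05
    boundary: float = 90.0  # vertical axis

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must be in [0, 1]")


# ---------------------------------------------------------------------------
# Trial schedule
# ---------------------------------------------------------------------------

def design_session(config: SessionConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Balanced pseudo-random schedule of 8 directions x {hom, het}.

    No two consecutive trials share both the mean direction and the variance
    condition.  Implemented as shuffle + targeted repair swaps with a restart
    cap; raises if the constraint is unsatisfiable (one trial type holding
    more than half of all slots).
    """
    dirs = list(config.direction_set)
    types = [(d, c) for c in ("hom", "het") for d in dirs]
    seq = np.repeat(np.arange(len(types)), config.trials_per_direction)
    n = seq.size
    counts = np.bincount(seq)
    if counts.max() > (n + 1) // 2:
        raise ValueError("adjacency constraint unsatisfiable for this configuration")

    def violations(s):
        return np.flatnonzero(s[1:] == s[:-1]) + 1

    ok = False
    for _restart in range(50):
        s = rng.permutation(seq)
        for _ in range(20 * n):
            bad = violations(s)
            if bad.size == 0:
                ok = True
                break
            i = int(bad[0])
            j = int(rng.integers(n))
            s[i], s[j] = s[j], s[i]
        if ok:
            break
    if not ok:
        raise RuntimeError("could not satisfy adjacency constraint (retry cap hit)")

    rows = []
    for t, k in enumerate(s):
        d, c = types[k]
        rows.append(
            {
                "trial_id": t,
                "variance_condition": c,
                "het_range": 0.0 if c == "hom" else float(config.het_range),
                "mean_direction": float(d),
                "category": category_of(d),
                "onset_frame": t * config.frames_per_trial + config.pre_frames,
                "choice": "none",
                "correct": False,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stimulus
# ---------------------------------------------------------------------------

def sample_dot_directions(
    mean: float, range_: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Dot directions: uniform on [mean - r/2, mean + r/2], wrapped to [0, 360).

    ``range_ == 0`` returns ``n`` copies of the mean.  For ``range_ > 0`` any
    draw exactly equal to the mean is rejected and resampled, so no single dot
    ever carries the global direction itself.
    """
    if not 0.0 <= range_ < 360.0:
        raise ValueError("range must be in [0, 360)")
    if n < 1:
        raise ValueError("n must be >= 1")
    if range_ == 0.0:
        return np.full(n, wrap360(mean))
    out = wrap360(mean + rng.uniform(-range_ / 2.0, range_ / 2.0, n))
    mean_w = float(wrap360(mean))
    bad = out == mean_w
    while bad.any():
        out[bad] = wrap360(mean + rng.uniform(-range_ / 2.0, range_ / 2.0, int(bad.sum())))
        bad = out == mean_w
    return out


# ---------------------------------------------------------------------------
# Rates, calcium, choices
# ---------------------------------------------------------------------------

def _attract_toward_center(theta: float, attraction: float) -> float:
    """Shift an angle toward its nearest horizontal category center.

    The shift is capped so the represented direction never overshoots the
    center itself.
    """
    center = nearest_category_center(theta)
    delta = float(wrap180(center - theta))
    step = np.sign(delta) * min(abs(delta), attraction)
    return float(wrap360(theta + step))


def simulate_trial_rates(
    trial, dots: np.ndarray, pop: PopulationModel, config: SessionConfig
) -> np.ndarray:
    """Neurons x frames rate array for one trial (pre + stimulus + post).

    Pre-stimulus frames sit at baseline; stimulus frames at the mode-dependent
    rate described in the module docstring.
    """
    n = pop.n_neurons
    rates = np.tile(pop.baseline[:, None], (1, config.frames_per_trial))
    mode = pop.coding_mode
    if mode == "untuned":
        stim = pop.baseline
    elif mode == "category":
        pref_cat = category_of(pop.preferred_direction)
        match = pref_cat == trial["category"]
        stim = pop.baseline + pop.amplitude * match
    elif mode == "linear_sum":
        # mean over dots of each neuron's tuning at the dot direction
        stim = pop.baseline + pop.amplitude * pop.tuning(np.asarray(dots, float)).mean(axis=0)
    elif mode == "sharpened_mean":
        mu = circmean_deg(dots)
        if pop.attraction_deg > 0:
            mu = _attract_toward_center(mu, pop.attraction_deg)
        gain = pop.gain_by_range.get(float(trial["het_range"]), 1.0)
        stim = pop.baseline + gain * pop.amplitude * pop.tuning(mu)[0]
    else:  # pragma: no cover - guarded in PopulationModel
        raise ValueError(f"unknown coding_mode {mode!r}")
    stim_slice = slice(config.pre_frames, config.pre_frames + config.stim_frames)
    rates[:, stim_slice] = np.broadcast_to(
        np.asarray(stim, float)[:, None], (n, config.stim_frames)
    )
    return rates


def simulate_calcium(
    rates: np.ndarray,
    params: CalciumParams,
    rng: np.random.Generator,
    frame_rate: float = 30.0,
) -> np.ndarray:
    """Convolve rates with a causal exponential kernel; add drift and noise.

    The kernel is exp(-t/tau) with unit value at lag zero, so a unit impulse
    produces a trace peaking at the impulse frame and decaying with tau.
    Drift is a slow sinusoid with a random phase per neuron.
    """
    rates = np.asarray(rates, float)
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    a = np.exp(-1.0 / (params.decay_tau * frame_rate))
    # y[t] = x[t] + a y[t-1]  <=>  convolution with a^k
    traces = _signal.lfilter([1.0], [1.0, -a], rates, axis=1)
    n_neurons, n_frames = rates.shape
    t = np.arange(n_frames) / frame_rate
    if params.drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi, n_neurons)
        traces = traces + params.drift_amplitude * np.sin(
            2 * np.pi * t[None, :] / params.drift_period + phase[:, None]
        )
    else:
        rng.uniform(0, 2 * np.pi, n_neurons)  # keep stream alignment
    if params.noise_sd > 0:
        traces = traces + rng.normal(0.0, params.noise_sd, traces.shape)
    return traces


def simulate_choices(
    trials: pd.DataFrame, psych: PsychParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Fill ``choice`` / ``correct`` from the psychometric model.

    P(right) = (1 - lapse) * Phi(s / sigma) + lapse / 2, where s is the signed
    horizontal distance of the mean direction from the vertical boundary.
    """
    trials = trials.copy()
    s = signed_distance_from_boundary(trials["mean_direction"].to_numpy())
    p_right = (1.0 - psych.lapse) * norm.cdf(s / psych.sigma) + psych.lapse / 2.0
    right = rng.uniform(size=len(trials)) < p_right
    trials["choice"] = np.where(right, "right", "left")
    trials["correct"] = trials["choice"] == trials["category"]
    return trials


# ---------------------------------------------------------------------------
# End-to-end session
# ---------------------------------------------------------------------------

def generate_session(
    config: SessionConfig,
    pop: PopulationModel,
    calcium: CalciumParams | None = None,
    psych: PsychParams | None = None,
    seed: int | None = None,
) -> Session:
    """Design, stimulate, image, and behave: a complete synthetic session.

    A single seed fans out to independent per-stage generators (schedule,
    dots, calcium, choices) via ``numpy.random.SeedSequence.spawn``, so the
    whole session is reproducible and stages are independently re-runnable.
    """
    calcium = calcium or CalciumParams()
    psych = psych or PsychParams()
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng_sched, rng_dots, rng_ca, rng_choice = (np.random.default_rng(s) for s in ss.spawn(4))

    trials = design_session(config, rng_sched)
    n_frames = len(trials) * config.frames_per_trial + config.pre_frames
    rates = np.tile(pop.baseline[:, None], (1, n_frames))
    for _, tr in trials.iterrows():
        dots = sample_dot_directions(
            tr["mean_direction"], tr["het_range"], config.n_dots, rng_dots
        )
        block = simulate_trial_rates(tr, dots, pop, config)
        start = int(tr["onset_frame"]) - config.pre_frames
        rates[:, start : start + config.frames_per_trial] = block
    traces = simulate_calcium(rates, calcium, rng_ca, frame_rate=config.frame_rate)
    trials = simulate_choices(trials, psych, rng_choice)
    cfg = {
        "direction_set": [float(d) for d in config.direction_set],
        "het_range": float(config.het_range),
        "trials_per_direction": int(config.trials_per_direction),
        "n_dots": int(config.n_dots),
        "frame_rate": float(config.frame_rate),
        "stim_duration": float(config.stim_duration),
        "pre_window": float(config.pre_window),
        "seed": int(seed),
        "coding_mode": pop.coding_mode,
    }
    return Session(trials=trials, traces=traces, frame_rate=config.frame_rate, config=cfg)
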