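"""Synthetic acceptance benchmark: every quantity recomputed from scratch.

Each function generates its own inputs from the study conditions (8 mean
directions, 500 dots, balanced hom/het schedules, GCaMP-like traces), runs
the corresponding pipeline stage, and measures the result.  ``run_benchmark``
collects everything into a flat ``{name: {"value": ..., "n": ...}}`` mapping.

Problem sizes (neurons, trials, permutations, CV repeats) are scaled for a
single CPU; the statistical conditions are the module defaults.
"""

from __future__ import annotations

import numpy as np

from . import behavior, bias, decoding, preprocess, prc, rsa, stats, synth, tuning
from ._angles import DIRECTION_SET
from .epochs import trial_window_mean

QUIET_CALCIUM = synth.CalciumParams(noise_sd=0.0, drift_amplitude=0.0)
#: default SNR of the synthetic sessions used for recovery studies
DEFAULT_CALCIUM = synth.CalciumParams(noise_sd=0.3, drift_amplitude=0.05)


def _seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _small_session(
    seed: int,
    n_neurons: int = 24,
    trials_per_direction: int = 5,
    coding_mode: str = "sharpened_mean",
    calcium: synth.CalciumParams = DEFAULT_CALCIUM,
    het_range: float = 180.0,
    attraction_deg: float = 0.0,
    amplitude: float = 1.0,
    jitter_pref: float = 0.0,
    amplitude_cv: float = 0.0,
    psych: synth.PsychParams | None = None,
):
    cfg = synth.SessionConfig(
        het_range=het_range, trials_per_direction=trials_per_direction, seed=seed
    )
    rng = np.random.default_rng(seed)
    pop = synth.make_population(
        n_neurons, rng, coding_mode=coding_mode, amplitude=amplitude, width=2.0,
        baseline=0.1, attraction_deg=attraction_deg,
        jitter_pref=jitter_pref, amplitude_cv=amplitude_cv,
    )
    psych = psych or synth.PsychParams(sigma=22.5, lapse=0.02)
    return synth.generate_session(cfg, pop, calcium, psych, seed=seed)


# ---------------------------------------------------------------------------
# Session design and stimulus configuration
# ---------------------------------------------------------------------------

def session_design_quantities(seed: int) -> dict:
    cfg = synth.SessionConfig(seed=seed)
    trials = synth.design_session(cfg, np.random.default_rng(seed))
    same_dir = trials["mean_direction"].to_numpy()[1:] == trials["mean_direction"].to_numpy()[:-1]
    same_var = (
        trials["variance_condition"].to_numpy()[1:]
        == trials["variance_condition"].to_numpy()[:-1]
    )
    n_types = trials.groupby(["mean_direction", "variance_condition"]).ngroups
    return {
        "n_hom_trials": {"value": int((trials["variance_condition"] == "hom").sum()),
                         "n": len(trials)},
        "n_het_trials": {"value": int((trials["variance_condition"] == "het").sum()),
                         "n": len(trials)},
        "n_trial_types": {"value": int(n_types), "n": len(trials)},
        "adjacency_violations": {"value": int((same_dir & same_var).sum()),
                                 "n": len(trials) - 1},
    }


def stimulus_quantities(seed: int) -> dict:
    cfg = synth.SessionConfig(seed=seed)
    rng = np.random.default_rng(seed)
    dots = synth.sample_dot_directions(22.5, cfg.het_range, cfg.n_dots, rng)
    dirs = np.asarray(cfg.direction_set)
    return {
        "n_dots_per_trial": {"value": int(dots.size), "n": int(dots.size)},
        "n_directions": {"value": int(dirs.size), "n": int(dirs.size)},
        "direction_min_deg": {"value": float(dirs.min()), "n": int(dirs.size)},
        "direction_max_deg": {"value": float(dirs.max()), "n": int(dirs.size)},
        "direction_step_deg": {"value": float(np.diff(np.sort(dirs)).mean()),
                               "n": int(dirs.size)},
    }


# ---------------------------------------------------------------------------
# Statistical calibration
# ---------------------------------------------------------------------------

def cluster_calibration(
    seed: int, n_datasets: int = 200, n_subjects: int = 10, n_bins: int = 100,
    n_perm: int = 500,
) -> dict:
    """Family-wise false-positive rate of the 1-D cluster test under pure null."""
    rng = np.random.default_rng(seed)
    fp = 0
    for _ in range(n_datasets):
        data = rng.normal(size=(n_subjects, n_bins))
        res = stats.cluster_perm_1d(data, n_perm=n_perm, rng=rng)
        fp += int(res.any_significant)
    return {
        "cluster_test_fwer": {"value": fp / n_datasets, "n": n_datasets},
    }


def svm_chance(seed: int, n_runs: int = 50) -> dict:
    """Variance-SVM accuracy on label-shuffled data (stimulus-window mean)."""
    session = _small_session(seed, n_neurons=20, trials_per_direction=5)
    X = trial_window_mean(session.traces, session.trials, session.frame_rate, 0.0, 4.0)
    y = (session.trials["variance_condition"] == "het").to_numpy()
    rng = np.random.default_rng(seed + 1)
    accs = []
    for _ in range(n_runs):
        accs.append(decoding._loo_accuracy(X, rng.permutation(y)))
    return {
        "shuffled_variance_svm_accuracy": {"value": float(np.mean(accs)), "n": n_runs},
    }


# ---------------------------------------------------------------------------
# IEM algebra and dynamics
# ---------------------------------------------------------------------------

def iem_quantities(seed: int) -> dict:
    rng = np.random.default_rng(seed)
    W = rng.normal(size=(20, 8))
    directions = np.repeat(DIRECTION_SET, 8)
    C = decoding.make_basis(directions)
    B = W @ C
    model = decoding.iem_fit(B, C)
    C2 = decoding.iem_invert(model, B)
    roundtrip = float(np.abs(C2 - C).max())

    # near-noiseless sessions (exact-zero noise would make pre-stimulus
    # activity rank one, a degenerate regression problem rather than a
    # flat-CTF case); the pre-stimulus slope is averaged over sessions since
    # a single inversion of uninformative activity is noisy
    n_sessions = 8
    stim_slopes, pre_slopes = [], []
    for s in _seeds(seed, n_sessions):
        session = _small_session(
            s, n_neurons=24, trials_per_direction=20,
            calcium=synth.CalciumParams(noise_sd=0.05, drift_amplitude=0.0),
        )
        series = decoding.iem_timecourse(
            session.traces, session.trials, session.frame_rate, decimate=15
        ).series
        stim = series["time"] >= 0.5  # clear of the calcium onset transient
        pre = series["time"] < 0
        stim_slopes.append(series.loc[stim, "slope_hom"].mean())
        pre_slopes.append(series.loc[pre, "slope_hom"].mean())
    return {
        "iem_roundtrip_error": {"value": roundtrip, "n": int(C.shape[1])},
        "ctf_slope_stimulus": {"value": float(np.mean(stim_slopes)),
                               "n": n_sessions},
        "ctf_slope_prestimulus": {"value": float(np.mean(pre_slopes)),
                                  "n": n_sessions},
    }


# ---------------------------------------------------------------------------
# Linear-summation attenuation
# ---------------------------------------------------------------------------

def _cosine_curves(n_neurons: int = 16, amplitude: float = 1.0) -> tuning.TuningCurves:
    dirs = np.asarray(DIRECTION_SET)
    prefs = np.array([dirs[i % 8] for i in range(n_neurons)])
    R = 1.0 + amplitude * np.cos(np.deg2rad(dirs[None, :] - prefs[:, None]))
    pref_idx = R.argmax(axis=1)
    return tuning.TuningCurves(
        directions=dirs, responses=R, condition="hom",
        preferred_direction=dirs[pref_idx],
        tie_flag=np.zeros(n_neurons, bool),
        dsi=tuning.dsi(R), slope=tuning.tuning_slope(R),
        selective=np.ones(n_neurons, bool),
        null_slope_95=np.zeros(n_neurons),
    )


def attenuation_quantities(seed: int) -> dict:
    curves = _cosine_curves()
    rng = np.random.default_rng(seed)
    base = tuning.simulate_het_tuning(curves, 0.0, n_match=16, n_resample=200, rng=rng)
    a0 = float(np.mean(base["peak_amplitudes"]))
    out = {}
    for r, name in ((180.0, "attenuation_range180"), (360.0, "attenuation_range360")):
        rng = np.random.default_rng(seed)
        sim = tuning.simulate_het_tuning(curves, r, n_match=16, n_resample=200, rng=rng)
        out[name] = {"value": float(np.mean(sim["peak_amplitudes"]) / a0), "n": 200}
    return out


# ---------------------------------------------------------------------------
# Wrapped-normal recovery and categorical bias
# ---------------------------------------------------------------------------

def wrapped_normal_recovery(seed: int) -> dict:
    # noiseless self-consistency, including the wrap-adjacent peak
    errs = []
    theta = np.arange(0.0, 360.0, 45.0) + 22.5
    for mu_true in (67.5, 337.5):
        y = 0.8 * bias.wrapped_normal_density(theta, mu_true, 40.0) + 0.2
        fit = bias.fit_wrapped_normal(theta, y)
        errs.append(abs(float(bias.wrap180(fit.mu - mu_true))))
    noiseless = max(errs)

    # default-SNR recovery of the PRC peak, no injected bias
    session = _small_session(seed, n_neurons=40, trials_per_direction=10)
    pref, _ = prc.preferred_direction_map(
        session.traces, session.trials, session.frame_rate, "hom"
    )
    tensor = prc.build_prc(
        session.traces, session.trials, session.frame_rate, pref, "hom", decimate=15
    )
    table = bias.estimate_session_bias(tensor)
    snr_err = float(np.nanmean(np.abs(table["raw_difference"])))
    return {
        "wrapped_normal_mu_error_noiseless_deg": {"value": noiseless, "n": 8},
        "wrapped_normal_mu_error_snr_deg": {"value": snr_err, "n": len(table)},
    }


def bias_recovery(seed: int, deltas=(0.0, 5.0, 10.0)) -> dict:
    """Recover injected categorical attraction from the fitted PRC peaks."""
    out = {}
    worst = 0.0
    for delta in deltas:
        session = _small_session(
            seed + int(delta), n_neurons=40, trials_per_direction=10,
            attraction_deg=delta,
        )
        pref, _ = prc.preferred_direction_map(
            session.traces, session.trials, session.frame_rate, "hom"
        )
        tensor = prc.build_prc(
            session.traces, session.trials, session.frame_rate, pref, "hom",
            decimate=15,
        )
        table = bias.estimate_session_bias(tensor)
        est = float(np.nanmean(table["signed_bias"]))
        out[f"categorical_bias_injected_{int(delta)}_deg"] = {
            "value": est, "n": int(table["converged"].sum())
        }
        worst = max(worst, abs(est - delta))
    out["categorical_bias_recovery_error_deg"] = {"value": worst, "n": len(deltas)}
    return out


# ---------------------------------------------------------------------------
# RSA / WCD-BCD dissociation
# ---------------------------------------------------------------------------

#: population response amplitude for the RSA / WCD-BCD recovery subjects:
#: chosen so pairwise decoding stays graded (clear of ceiling), the regime in
#: which the RDM regression is informative
RSA_AMPLITUDE = 0.003


def _subject_betas_and_wcdbcd(seed: int, coding_mode: str, n_synth: int = 40):
    session = _small_session(
        seed, n_neurons=24, trials_per_direction=16, coding_mode=coding_mode,
        amplitude=RSA_AMPLITUDE, jitter_pref=10.0, amplitude_cv=0.3,
    )
    rng = np.random.default_rng(seed + 7)
    pseudo = rsa.pseudo_trials(
        session.traces, session.trials, session.frame_rate,
        n_synth=n_synth, rng=rng, decimate=15,
    )
    betas = rsa.regress_rdm(rsa.rdm_timecourse(pseudo), rsa.build_model_rdms())
    wb = decoding.wcd_bcd(
        session.traces, session.trials, session.frame_rate,
        n_repeats=10, rng=rng,
    )
    diff = float((wb["diff_hom"].iloc[0] + wb["diff_het"].iloc[0]) / 2.0)
    return pseudo.times, betas, diff


def dissociation(seed: int, n_subjects: int = 10) -> dict:
    """Group-level RSA betas and BCD-WCD for direction- vs category-coding
    populations: the in-silico analogue of the cortical-hierarchy contrast."""
    out = {}
    for mode, tag in (("sharpened_mean", "direction_code"), ("category", "category_code")):
        b_mean, b_cat, diffs = [], [], []
        times = None
        for s in _seeds(seed + (0 if mode == "sharpened_mean" else 1), n_subjects):
            times, betas, diff = _subject_betas_and_wcdbcd(s, mode)
            b_mean.append(betas["beta_mean"].to_numpy())
            b_cat.append(betas["beta_category"].to_numpy())
            diffs.append(diff)
        stim = times >= 0
        rng = np.random.default_rng(seed + 99)
        sig_mean = stats.cluster_perm_1d(
            np.asarray(b_mean), n_perm=500, rng=rng
        ).significant[stim].any()
        sig_cat = stats.cluster_perm_1d(
            np.asarray(b_cat), n_perm=500, rng=rng
        ).significant[stim].any()
        out[f"rsa_beta_mean_significant_{tag}"] = {
            "value": float(sig_mean), "n": n_subjects
        }
        out[f"rsa_beta_category_significant_{tag}"] = {
            "value": float(sig_cat), "n": n_subjects
        }
        out[f"bcd_minus_wcd_{tag}"] = {
            "value": float(np.mean(diffs)), "n": n_subjects
        }
    return out


# ---------------------------------------------------------------------------
# Preprocessing toys
# ---------------------------------------------------------------------------

def make_transient_trace(
    n_frames: int = 3000,
    transient_frames=(500, 1500, 2500),
    amplitude: float = 1.0,
    noise_half_width: float = 0.02,
    seed: int = 0,
    mirror_negative: bool = False,
) -> np.ndarray:
    """Toy trace: tiny bounded symmetric noise plus well-separated transients.

    Uniform noise on [-a, a] has mirrored-negative IQR a, so the 3xIQR
    threshold (3a) can never be crossed by noise alone -- the injected
    transients are provably the only events.  Transients are square pulses,
    so the bounded noise can neither split a pulse into several threshold
    crossings nor create crossings of its own.
    """
    rng = np.random.default_rng(seed)
    x = rng.uniform(-noise_half_width, noise_half_width, n_frames)
    for f in transient_frames:
        x[f : f + 30] += amplitude
    if mirror_negative:
        for f in transient_frames:
            x[f + 120 : f + 150] -= amplitude
    return x


def preprocessing_quantities(seed: int) -> dict:
    trace = make_transient_trace(seed=seed)
    res = preprocess.detect_events_and_qc(trace[None, :])
    bad = make_transient_trace(seed=seed + 1, mirror_negative=True)
    res_bad = preprocess.detect_events_and_qc(bad[None, :])
    return {
        "toy_positive_events_detected": {"value": int(res.n_positive_events[0]),
                                         "n": 3},
        "toy_clean_trace_qc_pass": {"value": float(res.qc_pass[0]), "n": 1},
        "toy_mirrored_trace_qc_pass": {"value": float(res_bad.qc_pass[0]), "n": 1},
    }


# ---------------------------------------------------------------------------

def run_benchmark(seed: int = 1) -> dict:
    """Compute every benchmark quantity; returns {name: {value, n}}."""
    s = _seeds(seed, 9)
    out = {}
    out.update(session_design_quantities(s[0]))
    out.update(stimulus_quantities(s[1]))
    out.update(preprocessing_quantities(s[2]))
    out.update(attenuation_quantities(s[3]))
    out.update(iem_quantities(s[4]))
    out.update(wrapped_normal_recovery(s[5]))
    out.update(bias_recovery(s[6]))
    out.update(svm_chance(s[7]))
    out.update(cluster_calibration(s[8]))
    out.update(dissociation(seed))
    return out
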