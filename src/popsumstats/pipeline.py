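"""End-to-end orchestration: session in, results tree + run manifest out.

Stage order: preprocess -> behavior -> tuning -> prc -> bias -> decoding ->
rsa.  Every output file is listed in ``manifest.json`` with a content hash,
so a rerun with the same seed is verifiable bit-for-bit.  A single master
seed fans out to per-stage generators via ``SeedSequence.spawn``; each stage
is therefore independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
import time

import numpy as np
import pandas as pd

from . import behavior, bias, decoding, prc, preprocess, rsa, tuning
from .io import Session, load_session

#: pipeline-level analysis sizes; the statistical conditions (thresholds,
#: direction sets, CV schemes) live in the stage modules themselves.
DEFAULT_CONFIG = {
    "preprocess_window": 900,
    "selectivity_n_perm": 1000,
    "decimate": 6,  # 30 Hz frames -> 5 Hz analysis bins
    "wcd_bcd_repeats": 10,
    "rsa_n_synth": 60,
    "run_preprocess": True,
}


def _sha256(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(
    session: Session | str | pathlib.Path,
    out_dir,
    seed: int = 0,
    config: dict | None = None,
) -> dict:
    """Run every analysis stage on a session; returns the manifest dict."""
    if not isinstance(session, Session):
        session = load_session(session)
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    rngs = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ["tuning", "decoding", "rsa"], ss.spawn(3)
        )
    }
    fr = session.frame_rate
    dec = int(cfg["decimate"])
    manifest = {"seed": int(seed), "config": cfg, "stages": {}}

    def record(stage: str, t0: float, files: list[pathlib.Path]):
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": {f.name: _sha256(f) for f in files},
        }

    # --- preprocess -------------------------------------------------------
    t0 = time.perf_counter()
    traces = session.traces
    files = []
    if cfg["run_preprocess"]:
        traces = preprocess.clean_traces(traces, window_frames=int(cfg["preprocess_window"]))
        ev = preprocess.detect_events_and_qc(traces)
        qc_path = out / "qc.csv"
        ev.report().to_csv(qc_path, index=False)
        files.append(qc_path)
    record("preprocess", t0, files)

    # --- behavior ---------------------------------------------------------
    t0 = time.perf_counter()
    summ = behavior.summarize_behavior(session.trials)
    f1, f2 = out / "behavior_per_direction.csv", out / "dprime.csv"
    summ["per_direction"].to_csv(f1, index=False)
    summ["dprime_table"].to_csv(f2, index=False)
    psych_rows = []
    for cond in ("hom", "het"):
        sub = session.trials[session.trials["variance_condition"] == cond]
        res = behavior.PsychometricModel.from_trials(sub).fit()
        psych_rows.append(
            {"condition": cond, "mu": res.mu, "sigma": res.sigma,
             "slope": res.slope, "n_trials": res.n_trials}
        )
    f3 = out / "psychometric.csv"
    pd.DataFrame(psych_rows).to_csv(f3, index=False)
    record("behavior", t0, [f1, f2, f3])

    # --- tuning -----------------------------------------------------------
    t0 = time.perf_counter()
    curves = {}
    files = []
    for cond in ("hom", "het"):
        tc = tuning.compute_tuning(traces, session.trials, fr, cond)
        tc = tuning.classify_selective(
            tc, traces, session.trials, fr,
            n_perm=int(cfg["selectivity_n_perm"]), rng=rngs["tuning"],
        )
        curves[cond] = tc
        f = out / f"tuning_{cond}.csv"
        tc.to_frame().to_csv(f, index=False)
        files.append(f)
    record("tuning", t0, files)

    # --- prc --------------------------------------------------------------
    t0 = time.perf_counter()
    slope_frames = []
    prcs = {}
    for cond in ("hom", "het"):
        pref, _ = prc.preferred_direction_map(traces, session.trials, fr, cond)
        tensor = prc.build_prc(traces, session.trials, fr, pref, cond, decimate=dec)
        prcs[cond] = tensor
        slope_frames.append(prc.prc_slope(tensor))
    f1 = out / "prc_slopes.csv"
    pd.concat(slope_frames).to_csv(f1, index=False)
    f2 = out / "subset_slopes.csv"
    n = session.n_neurons
    feasible = [p for p in (10, 50, 95, 100) if np.ceil(p / 100.0 * n) >= 8]
    prc.subset_prc(
        traces, session.trials, fr, curves["hom"].slope, "hom",
        percents=feasible, decimate=dec,
    ).to_csv(f2, index=False)
    record("prc", t0, [f1, f2])

    # --- bias -------------------------------------------------------------
    t0 = time.perf_counter()
    bias_frames = []
    for cond in ("hom", "het"):
        b = bias.estimate_session_bias(prcs[cond])
        b["condition"] = cond
        bias_frames.append(b)
    f1 = out / "bias.csv"
    pd.concat(bias_frames).to_csv(f1, index=False)
    record("bias", t0, [f1])

    # --- decoding ---------------------------------------------------------
    t0 = time.perf_counter()
    iem = decoding.iem_timecourse(traces, session.trials, fr, decimate=dec)
    f1 = out / "iem_slopes.csv"
    iem.series.to_csv(f1, index=False)
    svm_var = decoding.svm_condition_timecourse(
        traces, session.trials, fr, label="variance", decimate=dec
    )
    f2 = out / "svm_variance.csv"
    svm_var.series.to_csv(f2, index=False)
    svm_cat = decoding.svm_condition_timecourse(
        traces, session.trials, fr, label="category", decimate=dec
    )
    f3 = out / "svm_category.csv"
    svm_cat.series.to_csv(f3, index=False)
    wb = decoding.wcd_bcd(
        traces, session.trials, fr,
        n_repeats=int(cfg["wcd_bcd_repeats"]), rng=rngs["decoding"],
    )
    f4 = out / "wcd_bcd.csv"
    wb.to_csv(f4, index=False)
    record("decoding", t0, [f1, f2, f3, f4])

    # --- rsa --------------------------------------------------------------
    t0 = time.perf_counter()
    pseudo = rsa.pseudo_trials(
        traces, session.trials, fr,
        n_synth=int(cfg["rsa_n_synth"]), rng=rngs["rsa"], decimate=dec,
    )
    neural = rsa.rdm_timecourse(pseudo)
    betas = rsa.regress_rdm(neural, rsa.build_model_rdms())
    betas.insert(0, "time", pseudo.times)
    f1 = out / "rsa_betas.csv"
    betas.to_csv(f1, index=False)
    record("rsa", t0, [f1])

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
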