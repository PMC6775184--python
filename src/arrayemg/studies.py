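"""Canonical simulation studies exercising the pipeline end to end.

Each study fixes its problem size to something a single CPU handles in
minutes while keeping the statistical structure of the full protocol; the
sizes are stated in the docstrings and in the methods note.  All studies
are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .evaluate import EvalTable, _resample_rows, correlation_coefficient, rmse, run_protocol
from .kinematics import FINGERS, FingerTrajectory, NrmsdSeries, finger_angle_from_trigger
from .layout import ArrayLayout, ChannelMask
from .models import fit_lrm, fit_msm, msm_predict
from .preprocess import EnvelopeSet, envelope, preprocess_pipeline
from .simulate import (
    FS_TRUTH,
    SimConfig,
    _truth_series,
    draw_subject_params,
    generate_activations,
    generate_protocol,
    iter_subjects,
    make_subject,
    source_mixing,
    synthesize_emg,
)
from . import sources as _sources


def msm_recovery_study(seed: int = 0, restarts: int = 10) -> dict:
    """Fit the equilibrium decoder on noiseless simulator output.

    For each finger: generate two short train experiments (3 motions each)
    of true activations and equilibrium angles, fit on the first and score
    predictions on the held-out second.  Returns per-finger held-out CC
    and RMSE (rad) plus the worst case over fingers.
    """
    cfg = SimConfig(seed=seed, fs_raw=1024.0, motions_per_train_exp=3, crosstalk=0.0)
    rng = np.random.default_rng(seed)
    params = draw_subject_params(rng)
    out = {}
    for i, finger in enumerate(FINGERS):
        sched = generate_protocol(cfg, "train", finger)
        series = []
        for rep in range(2):
            acts = generate_activations(sched, cfg, rng_seed=seed * 1000 + 10 * i + rep)
            u, angles, _ = _truth_series(acts, params, sched, cfg)
            series.append((u[0, i], u[1, i], angles[i]))
        (u1_tr, u2_tr, th_tr), (u1_te, u2_te, th_te) = series
        fit = fit_msm(u1_tr, u2_tr, th_tr, restarts=restarts, seed=seed)
        pred = msm_predict(u1_te, u2_te, fit.params)
        out[finger] = {
            "cc": correlation_coefficient(pred, th_te),
            "rmse_rad": rmse(pred, th_te),
        }
    out["min_cc"] = min(v["cc"] for k, v in out.items() if k in FINGERS)
    out["max_rmse_rad"] = max(v["rmse_rad"] for k, v in out.items() if k in FINGERS)
    return out


def lrm_recovery_study(seed: int = 0) -> dict:
    """Recover planted OLS coefficients from exactly linear data.

    Activations come from one simulated train experiment; the angle is an
    exact linear combination theta = b0 + b1 u1 + b2 u2.  Returns the
    planted and recovered coefficients and their max absolute error.
    """
    cfg = SimConfig(seed=seed, fs_raw=1024.0, motions_per_train_exp=3, crosstalk=0.0)
    sched = generate_protocol(cfg, "train", "Index")
    rng = np.random.default_rng(seed)
    params = draw_subject_params(rng)
    acts = generate_activations(sched, cfg, rng_seed=seed + 7)
    u, _, _ = _truth_series(acts, params, sched, cfg)
    u1, u2 = u[0, 1], u[1, 1]
    beta = (0.5, 2.0, -1.0)
    theta = beta[0] + beta[1] * u1 + beta[2] * u2
    fit = fit_lrm(u1, u2, theta)
    est = (fit.params.beta0, fit.params.beta1, fit.params.beta2)
    return {
        "beta_true": beta,
        "beta_est": est,
        "max_abs_err": float(max(abs(a - b) for a, b in zip(beta, est))),
    }


def ica_separation_study(seed: int = 0, n_seeds: int = 5, duration: float = 60.0, fs: float = 500.0) -> list[dict]:
    """Separate known super-Gaussian mixtures and score the Amari index.

    Each run mixes 3–6 independent Laplacian sources through a random
    well-conditioned matrix into 8 channels (60 s at 500 Hz) and reports
    the Amari index of the fitted unmixing against the true mixing.
    """
    results = []
    n = int(duration * fs)
    for k in range(n_seeds):
        run_seed = seed * 100 + k
        rng = np.random.default_rng(run_seed)
        n_src = 3 + k % 4
        S = rng.laplace(size=(n_src, n))
        while True:
            A = rng.normal(size=(8, n_src))
            if np.linalg.cond(A) < 20:
                break
        X = A @ S
        decomp = _sources.fit_ica(X, n_components=n_src, seed=run_seed, fs=fs)
        results.append(
            {
                "seed": run_seed,
                "n_sources": n_src,
                "amari": _sources.amari_index(decomp.unmixing, A),
                "converged": decomp.converged,
            }
        )
    return results


def selection_study(seed: int = 0, n_seeds: int = 5, snr_db: float = 10.0) -> list[dict]:
    """Select per-finger/direction ICs and score them against the truth.

    Per run: one simulated subject, one short train experiment per finger
    (2 motions, 1024 Hz raw), preprocessing, a 16-component ICA on the
    concatenated data, component ranking per (finger, direction), then the
    |CC| between each chosen component's envelope and the generating
    muscle activation.  Returns the per-run minimum |CC| over the ten
    (finger, direction) slots.
    """
    layout = ArrayLayout.default()
    fs_model = 25.0
    results = []
    for k in range(n_seeds):
        run_seed = seed * 100 + k
        cfg = SimConfig(
            seed=run_seed,
            fs_raw=1024.0,
            motions_per_train_exp=2,
            train_exps_per_finger=1,
            test_exps=1,
            crosstalk=0.1,
            snr_db=snr_db,
            artifact_level=0.2,
        )
        rng = np.random.default_rng(run_seed)
        params = draw_subject_params(rng)
        mixing, _ = source_mixing(layout)
        procs, gts, acts_list = [], [], []
        for i, finger in enumerate(FINGERS):
            sched = generate_protocol(cfg, "train", finger)
            acts = generate_activations(sched, cfg, rng_seed=run_seed * 50 + i)
            rec = synthesize_emg(acts, sched, layout, cfg, rng_seed=run_seed * 50 + i + 25, mixing=mixing)
            proc = preprocess_pipeline(rec)
            u, angles, nrmsd = _truth_series(acts, params, sched, cfg)
            traj = finger_angle_from_trigger(NrmsdSeries(nrmsd, FS_TRUTH), sched)
            procs.append(proc)
            gts.append(_resample_rows(traj.angles, FS_TRUTH, fs_model))
            acts_list.append(_resample_rows(u, FS_TRUTH, fs_model))
        X = np.concatenate([p.data for p in procs], axis=1)
        decomp = _sources.fit_ica(X, n_components=16, seed=run_seed, fs=procs[0].fs)
        env_ic = envelope(decomp.sources, decomp.fs, source_kind="independent_component")
        env_m = np.clip(_resample_rows(env_ic.envelopes, decomp.fs, fs_model), 0, None)
        gt_all = np.concatenate(gts, axis=-1)
        act_all = np.concatenate([np.clip(a, 0, None) for a in acts_list], axis=-1)
        n = min(env_m.shape[1], gt_all.shape[1], act_all.shape[2])
        traj_all = FingerTrajectory(gt_all[:, :n], fs=fs_model)
        env_set = EnvelopeSet(env_m[:, :n], fs_model, "independent_component")
        ccs = {}
        for i, finger in enumerate(FINGERS):
            for m, direction in ((0, "flexion"), (1, "extension")):
                sel = _sources.rank_components_by_cc(
                    decomp,
                    traj_all,
                    finger,
                    direction,
                    layout=layout,
                    component_envelopes=env_set,
                )
                cc = correlation_coefficient(env_m[sel.chosen, :n], act_all[m, i, :n])
                ccs[(finger, direction)] = abs(cc)
        results.append({"seed": run_seed, "min_abs_cc": min(ccs.values()), "cc": ccs})
    return results


def ic_advantage_study(
    seed: int = 0,
    n_subjects: int = 10,
    snr_db: float = 5.0,
    msm_restarts: int = 4,
) -> dict:
    """Directional IC-vs-EMG comparison of the equilibrium decoder.

    Ten simulated subjects with spatially overlapping muscle blobs,
    cross-talk 0.2 and 5 dB broadband SNR; per subject one train experiment
    per finger (3 motions, 1024 Hz) and two mixed test experiments (one
    cycle per finger).  Protocol A is run for MSM-ICA and MSM-EMG with a
    24-component ICA, and the study reports the mean CC of each route and
    their difference across subjects × fingers.
    """
    cfg = SimConfig(
        seed=seed,
        n_subjects=n_subjects,
        fs_raw=1024.0,
        motions_per_train_exp=3,
        train_exps_per_finger=1,
        test_exps=2,
        cycles_per_test_exp=5,
        crosstalk=0.2,
        snr_db=snr_db,
        artifact_level=0.5,
    )
    table = run_protocol(
        iter_subjects(cfg),
        protocol="A",
        methods=("MSM-ICA", "MSM-EMG"),
        ica_components=24,
        ica_seed=seed,
        msm_restarts=msm_restarts,
        msm_seed=seed,
    )
    df = table.table
    mean_ic = float(df[df["method"] == "MSM-ICA"]["cc"].mean())
    mean_emg = float(df[df["method"] == "MSM-EMG"]["cc"].mean())
    return {
        "table": table,
        "mean_cc_ic": mean_ic,
        "mean_cc_emg": mean_emg,
        "cc_advantage": mean_ic - mean_emg,
        "n_subjects": n_subjects,
    }
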