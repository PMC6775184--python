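"""Performance metrics and the train/test analysis protocols.

Two indicators compare a decoded finger-angle trajectory with ground truth:
the Pearson correlation coefficient computed with sample (n−1) standard
deviations,

    r = (1/(n−1)) Σ ((x−x̄)/S_x) ((y−ȳ)/S_y)

and the root-mean-square error sqrt(mean (x−y)^2); RMSE is reported in
degrees in result tables.  A classical paired t-test compares the CC of the
IC-based and channel-based variants of the same decoder across
(subject, finger) pairs.

``run_protocol`` reproduces the two analysis designs: Protocol A fits the
per-finger decoders on the single-finger train experiments and scores them
on the mixed-finger test experiments; Protocol B fits on exactly one mixed
test experiment and scores on the remaining ones (the small-training-data
regime).  Both are run for the four method combinations MSM/LRM × ICA/EMG.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as _sig
from scipy import stats

from .kinematics import FINGERS, FingerTrajectory, NrmsdSeries, finger_angle_from_trigger, smooth_trajectory
from .layout import ArrayLayout, ChannelMask
from .models import fit_lrm, fit_msm, lrm_predict, msm_predict
from .preprocess import EnvelopeSet, envelope, preprocess_pipeline, remove_calibration_offset

METHODS = ("MSM-ICA", "MSM-EMG", "LRM-ICA", "LRM-EMG")


# --------------------------------------------------------------------------
# metrics


def correlation_coefficient(x, y) -> float:
    """Sample Pearson correlation; NaN (flagged missing) on zero variance."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.sum((x - x.mean()) / sx * (y - y.mean()) / sy) / (n - 1))


def rmse(x, y) -> float:
    """Root-mean-square difference, in the units of the inputs."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if x.size < 1:
        raise ValueError("need at least 1 sample")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def paired_ttest(a, b) -> dict:
    """Classical paired t-test on d = a − b; two-sided p, df = n − 1."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if d.std(ddof=1) == 0:
        if np.allclose(d, 0):
            return {"t": 0.0, "df": n - 1, "p": 1.0, "undefined": False}
        return {"t": float("nan"), "df": n - 1, "p": float("nan"), "undefined": True}
    res = stats.ttest_rel(a, b)
    return {"t": float(res.statistic), "df": n - 1, "p": float(res.pvalue), "undefined": False}


# --------------------------------------------------------------------------
# result table


@dataclass
class EvalTable:
    """Per (subject, finger, method, protocol) CC and RMSE rows."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"subject", "finger", "method", "protocol", "cc", "rmse_deg"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"EvalTable missing columns {sorted(missing)}")
        cc = self.table["cc"].dropna()
        if np.any(np.abs(cc) > 1 + 1e-9):
            raise ValueError("|cc| must not exceed 1")
        if np.any(self.table["rmse_deg"].dropna() < 0):
            raise ValueError("rmse must be non-negative")

    def aggregate(self) -> pd.DataFrame:
        """Mean ± std across subjects per (finger, method, protocol)."""
        return (
            self.table.groupby(["protocol", "method", "finger"], sort=False)
            .agg(cc_mean=("cc", "mean"), cc_std=("cc", "std"),
                 rmse_mean=("rmse_deg", "mean"), rmse_std=("rmse_deg", "std"))
            .fillna({"cc_std": 0.0, "rmse_std": 0.0})
            .reset_index()
        )

    def report(self) -> str:
        """Formatted text report: one block per protocol, fingers as columns."""
        agg = self.aggregate()
        lines = []
        for proto in agg["protocol"].unique():
            lines.append(f"Protocol {proto} (RMSE in degrees)")
            header = f"{'method':<10}{'value':<12}" + "".join(f"{f:>10}" for f in FINGERS)
            lines.append(header)
            block = agg[agg["protocol"] == proto]
            for method in block["method"].unique():
                sel = block[block["method"] == method].set_index("finger")
                for stat, fmt in (("cc_mean", "CC mean"), ("cc_std", "CC std"),
                                  ("rmse_mean", "RMSE mean"), ("rmse_std", "RMSE std")):
                    row = f"{method:<10}{fmt:<12}"
                    for f in FINGERS:
                        v = sel.loc[f, stat] if f in sel.index else float("nan")
                        row += f"{v:>10.3f}"
                    lines.append(row)
            lines.append("")
        return "\n".join(lines)


def ic_emg_ttest(table: EvalTable, model: str = "MSM", protocol: str = "A") -> dict:
    """Paired t-test of CC between the IC and EMG variants of one decoder."""
    df = table.table
    sel = df[df["protocol"] == protocol]
    ic = sel[sel["method"] == f"{model}-ICA"].set_index(["subject", "finger"])["cc"]
    em = sel[sel["method"] == f"{model}-EMG"].set_index(["subject", "finger"])["cc"]
    common = ic.index.intersection(em.index)
    return paired_ttest(ic.loc[common].values, em.loc[common].values)


# --------------------------------------------------------------------------
# protocol harness


def _resample_rows(x: np.ndarray, fs_from: float, fs_to: float) -> np.ndarray:
    if fs_from == fs_to:
        return x
    frac = Fraction(fs_to / fs_from).limit_denominator(10000)
    return _sig.resample_poly(x, frac.numerator, frac.denominator, axis=-1)


def _ground_truth(exp, fs_model: float) -> np.ndarray:
    """Smoothed trigger×NRMSD trajectory, (5, n) at the model rate."""
    nr = NrmsdSeries(exp.truth.nrmsd, exp.truth.fs)
    traj = finger_angle_from_trigger(nr, exp.schedule)
    traj = smooth_trajectory(traj)
    return _resample_rows(traj.angles, traj.fs, fs_model)


def run_protocol(
    dataset,
    protocol: str = "A",
    methods: tuple[str, ...] = METHODS,
    *,
    layout: ArrayLayout | None = None,
    mask: ChannelMask | None = None,
    fs_proc: float = 500.0,
    fs_model: float = 25.0,
    ica_components: int | str = "auto",
    ica_seed: int = 0,
    msm_restarts: int = 10,
    msm_seed: int = 0,
    fit_variant: str = "caption",
) -> EvalTable:
    """Run one analysis protocol over a dataset of simulated subjects.

    ``dataset`` is a ``simulate.SimDataset`` or any iterable of
    ``simulate.SubjectData`` (a generator keeps memory flat for large
    cohorts).  Per subject: preprocess every experiment, fit one ICA on the
    concatenation of all its experiments, select per-finger
    flexor/extensor channels (anatomical mask + best envelope CC) and
    components (top-CC, topology-vetted), then fit and score the requested
    decoders.  Envelopes and ground truth are compared at ``fs_model``
    (envelope content lives below the 3-Hz cutoff, so 25 Hz loses nothing).

    ``fit_variant`` selects how Protocol A obtains its training data:
    ``'caption'`` (default) fits on the single-finger train experiments;
    ``'test_refit'`` fits on the concatenated test experiments themselves
    (the optimal-situation reading).
    """
    from . import sources as _sources  # deferred: sources uses this module's metrics

    if protocol not in ("A", "B"):
        raise ValueError("protocol must be 'A' or 'B'")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}")
    layout = layout or ArrayLayout.default()
    mask = mask or ChannelMask.default(layout)

    subjects = dataset.subjects if hasattr(dataset, "subjects") else dataset
    rows = []
    for sub in subjects:
        rows.extend(
            _run_subject(
                sub, protocol, methods, layout, mask, _sources,
                fs_proc, fs_model, ica_components, ica_seed,
                msm_restarts, msm_seed, fit_variant,
            )
        )
    return EvalTable(pd.DataFrame(rows))


def _run_subject(
    sub, protocol, methods, layout, mask, _sources,
    fs_proc, fs_model, ica_components, ica_seed,
    msm_restarts, msm_seed, fit_variant,
):
    exps = sub.experiments
    uids = [f"{e.kind}-{e.finger}-{i}" for i, e in enumerate(exps)]
    proc = [preprocess_pipeline(e.recording, fs_out=fs_proc) for e in exps]

    decomp = _sources.fit_ica(
        np.concatenate([p.data for p in proc], axis=1),
        n_components=ica_components,
        seed=ica_seed,
        fs=fs_proc,
    )

    need_emg = any(m.endswith("EMG") for m in methods)
    per_exp = []
    for e, p in zip(exps, proc):
        calib_end = e.schedule.phases[0].end
        entry = {"gt": _ground_truth(e, fs_model)}
        if need_emg:
            env = envelope(p.data, fs_proc, source_kind="raw_channel", ids=p.labels)
            env = remove_calibration_offset(env, calib_end)
            entry["emg"] = _resample_rows(env.envelopes, fs_proc, fs_model)
        ic_sig = decomp.transform(p.data)
        env_ic = envelope(ic_sig, fs_proc, source_kind="independent_component")
        env_ic = remove_calibration_offset(env_ic, calib_end)
        entry["ic"] = _resample_rows(env_ic.envelopes, fs_proc, fs_model)
        n = min(v.shape[-1] for v in entry.values())
        per_exp.append({k: np.clip(v[..., :n], 0.0, None) if k != "gt" else v[..., :n]
                        for k, v in entry.items()})

    train_idx = [i for i, e in enumerate(exps) if e.kind == "train"]
    test_idx = [i for i, e in enumerate(exps) if e.kind == "test"]
    if protocol == "B" and len(test_idx) < 2:
        raise ValueError("protocol B needs at least 2 test experiments")

    def concat(key, idxs):
        return np.concatenate([per_exp[i][key] for i in idxs], axis=-1)

    gt_train = FingerTrajectory(concat("gt", train_idx), fs=fs_model)
    selections = {}
    for finger in FINGERS:
        for direction in ("flexion", "extension"):
            sel_ic = _sources.rank_components_by_cc(
                decomp, gt_train, finger, direction, layout=layout,
                component_envelopes=EnvelopeSet(
                    concat("ic", train_idx), fs_model, "independent_component"
                ),
            )
            selections[("ICA", finger, direction)] = sel_ic.chosen
            if need_emg:
                env_set = EnvelopeSet(
                    concat("emg", train_idx), fs_model, "raw_channel",
                    ids=proc[0].labels,
                )
                sel_ch = _sources.select_channels(
                    env_set, gt_train, mask, finger, direction, layout=layout
                )
                selections[("EMG", finger, direction)] = sel_ch.chosen

    def u_pair(route, finger, idxs):
        key = "ic" if route == "ICA" else "emg"
        ids = list(range(decomp.n_components)) if route == "ICA" else list(proc[0].labels)
        i1 = ids.index(selections[(route, finger, "flexion")])
        i2 = ids.index(selections[(route, finger, "extension")])
        u = concat(key, idxs)
        return u[i1], u[i2]

    if protocol == "A":
        fit_idx = None  # per finger, below
        eval_idx = test_idx
    else:
        fit_idx = [test_idx[0]]
        eval_idx = test_idx[1:]

    rows = []
    for finger in FINGERS:
        if protocol == "A":
            if fit_variant == "caption":
                f_idx = [i for i in train_idx if exps[i].finger == finger]
            elif fit_variant == "test_refit":
                f_idx = test_idx
            else:
                raise ValueError(f"unknown fit_variant {fit_variant!r}")
        else:
            f_idx = fit_idx
        if fit_variant != "test_refit":
            assert not (set(f_idx) & set(eval_idx)), "test data leaked into fitting"
        theta_fit = concat("gt", f_idx)[FINGERS.index(finger)]
        for method in methods:
            model_kind, route = method.split("-")
            u1_fit, u2_fit = u_pair(route, finger, f_idx)
            norm1 = max(u1_fit.max(), 1e-9)
            norm2 = max(u2_fit.max(), 1e-9)
            if model_kind == "MSM":
                fit = fit_msm(u1_fit / norm1, u2_fit / norm2, theta_fit,
                              restarts=msm_restarts, seed=msm_seed)
                predict = lambda a, b, p=fit.params: msm_predict(a, b, p)
            else:
                fit = fit_lrm(u1_fit / norm1, u2_fit / norm2, theta_fit)
                predict = lambda a, b, p=fit.params: lrm_predict(a, b, p)
            ccs, errs = [], []
            for i in eval_idx:
                u1, u2 = u_pair(route, finger, [i])
                pred = predict(u1 / norm1, u2 / norm2)
                truth = per_exp[i]["gt"][FINGERS.index(finger)]
                ccs.append(correlation_coefficient(pred, truth))
                errs.append(np.degrees(rmse(pred, truth)))
            rows.append({
                "subject": sub.subject,
                "finger": finger,
                "method": method,
                "protocol": protocol,
                "cc": float(np.nanmean(ccs)),
                "rmse_deg": float(np.mean(errs)),
                "n_eval": len(eval_idx),
                "fit_ids": ",".join(uids[i] for i in f_idx),
                "eval_ids": ",".join(uids[i] for i in eval_idx),
            })
    return rows
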