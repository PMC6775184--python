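"""Synthetic array-EMG experiment generator with known ground truth.

Emulates the instructed finger-motion protocol on a 96-channel forearm
array: each motion is 2 s flexion, 2 s rest, 2 s extension, 2 s rest (8 s
total); a train experiment repeats 6 motions of one finger, a test
experiment cycles through all five fingers (two cycles each, ten total);
every experiment opens with a 4-s rest calibration segment.  Acquisition is
96 channels at 2048 Hz by default.

Per finger the generator draws subject-specific equilibrium-point model
parameters, scaled so that peak flexion/extension reach the protocol
trigger angles (≈2.094 / −0.523 rad).  Muscle contractions u(t) are smooth
trapezoidal bursts (raised-cosine ramps) with a small resting baseline;
adjacent fingers receive a configurable cross-talk fraction of the
instructed burst, mimicking the mechanical interconnection between finger
muscles.  Each muscle's surface EMG source is its contraction envelope
multiplied by an independent unit-RMS band-limited (20–250 Hz) noise
carrier — independent carriers make the sources statistically independent,
so the linear-mixing ICA model holds by construction.  Sources project onto
the electrode grid through Gaussian spatial blobs (σ = 1.5 grid units)
centred on each finger's anatomical mask block; mains interference, white
sensor noise (scaled to a configured broadband SNR) and low-frequency
motion-artifact bursts are added on top.

Everything is reproducible bit-for-bit from the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .kinematics import FingerTrajectory, NrmsdSeries, Phase, PhaseSchedule
from .layout import EXTENSOR, FINGERS, FLEXOR, ArrayLayout, mask_block_center
from .models import MsmParams, msm_equilibrium
from .preprocess import EmgRecording

BASELINE = 0.02  # resting contraction level
RAMP_S = 0.3  # raised-cosine ramp length of a burst
THETA_FLEX_TARGET = 2.094  # rad, peak flexion equilibrium
THETA_EXT_TARGET = -0.523  # rad, peak extension equilibrium
CARRIER_BAND = (20.0, 250.0)  # Hz, EMG carrier bandwidth
SOURCE_SIGMA = 1.5  # grid units, spatial spread of a muscle blob
FS_TRUTH = 250.0  # Hz, storage rate of ground-truth series


@dataclass
class SimConfig:
    """Study conditions for one synthetic acquisition campaign."""

    seed: int = 0
    n_subjects: int = 1
    fs_raw: float = 2048.0
    n_channels: int = 96
    phase_len: float = 2.0
    calibration_len: float = 4.0
    motions_per_train_exp: int = 6
    train_exps_per_finger: int = 5
    test_exps: int = 5
    cycles_per_test_exp: int = 10
    crosstalk: float = 0.15
    snr_db: float = 10.0
    line_freq: float = 50.0
    artifact_level: float = 0.5

    def validate(self) -> None:
        counts = (
            self.n_subjects,
            self.n_channels,
            self.motions_per_train_exp,
            self.train_exps_per_finger,
            self.test_exps,
            self.cycles_per_test_exp,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if self.phase_len <= 0 or self.calibration_len <= 0:
            raise ValueError("phase and calibration durations must be positive")
        if self.fs_raw <= 2 * self.carrier_band[1] or self.fs_raw < 512:
            raise ValueError(
                "fs_raw must exceed twice the carrier band edge (>= 512 Hz "
                "so the carrier keeps a usable EMG bandwidth)"
            )
        if not (0 <= self.crosstalk < 1):
            raise ValueError("crosstalk must lie in [0, 1)")
        if self.artifact_level < 0:
            raise ValueError("artifact_level must be non-negative")

    @property
    def carrier_band(self) -> tuple[float, float]:
        return (CARRIER_BAND[0], min(CARRIER_BAND[1], 0.45 * self.fs_raw))


@dataclass
class SimTruth:
    """Ground truth attached to one generated experiment.

    Series are stored at ``fs`` (default 250 Hz): ``activations`` has shape
    (2, 5, n) with axis 0 = (flexor, extensor); ``angles`` and ``nrmsd`` have
    shape (5, n).  ``angles`` is the equilibrium of ``params`` applied to
    ``activations`` at the stored rate.
    """

    params: list[MsmParams]
    activations: np.ndarray
    angles: np.ndarray
    nrmsd: np.ndarray
    fs: float
    mixing: np.ndarray  # channels × sources
    source_locations: dict


@dataclass
class Experiment:
    kind: str  # train | test
    finger: str | None
    schedule: PhaseSchedule
    recording: EmgRecording
    truth: SimTruth


@dataclass
class SubjectData:
    subject: int
    params: list[MsmParams]
    train: list[Experiment]
    test: list[Experiment]

    @property
    def experiments(self) -> list[Experiment]:
        return self.train + self.test


@dataclass
class SimDataset:
    config: SimConfig
    subjects: list[SubjectData]


# --------------------------------------------------------------------------
# protocol


def generate_protocol(cfg: SimConfig, kind: str, finger: str | None = None) -> PhaseSchedule:
    """Phase schedule of one experiment.

    ``kind='train'`` needs a finger: calibration rest then
    ``motions_per_train_exp`` cycles of [flex, rest, ext, rest].
    ``kind='test'`` cycles through all fingers Thumb→Pinky,
    ``cycles_per_test_exp`` cycles in total (two per finger by default).
    """
    cfg.validate()
    if kind == "train":
        if finger not in FINGERS:
            raise ValueError(f"unknown finger label {finger!r}")
        cycle_fingers = [finger] * cfg.motions_per_train_exp
    elif kind == "test":
        reps = max(1, int(round(cfg.cycles_per_test_exp / len(FINGERS))))
        seq = [f for f in FINGERS for _ in range(reps)]
        cycle_fingers = [seq[i % len(seq)] for i in range(cfg.cycles_per_test_exp)]
    else:
        raise ValueError(f"unknown experiment kind {kind!r}")

    phases = [Phase(0.0, cfg.calibration_len, "rest")]
    t = cfg.calibration_len
    d = cfg.phase_len
    for f in cycle_fingers:
        phases.append(Phase(t, t + d, "flexion", f))
        phases.append(Phase(t + d, t + 2 * d, "rest"))
        phases.append(Phase(t + 2 * d, t + 3 * d, "extension", f))
        phases.append(Phase(t + 3 * d, t + 4 * d, "rest"))
        t += 4 * d
    return PhaseSchedule(phases)


def motion_cycles(schedule: PhaseSchedule) -> int:
    """Number of flexion/rest/extension/rest motion cycles in a schedule."""
    return sum(1 for p in schedule.phases if p.kind == "flexion")


# --------------------------------------------------------------------------
# activations and subject parameters


def generate_activations(
    schedule: PhaseSchedule, cfg: SimConfig, rng_seed: int
) -> np.ndarray:
    """Per-finger flexor/extensor contraction series, shape (2, 5, n) at fs_raw.

    The instructed finger's flexor (during flexion) or extensor (during
    extension) ramps up with raised-cosine edges to an amplitude near 1;
    fingers adjacent in the anatomical order receive exactly
    ``crosstalk`` times the instructed burst.  Resting level is the
    baseline ε = 0.02 everywhere.
    """
    fs = cfg.fs_raw
    n = int(round(schedule.duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(rng_seed)
    bursts = np.zeros((2, len(FINGERS), n))  # (flex/ext, finger, time)
    for p in schedule.phases:
        if p.kind == "rest":
            continue
        muscle = 0 if p.kind == "flexion" else 1
        amp = rng.uniform(0.92, 1.0)
        ramp = min(RAMP_S, (p.end - p.start) / 3)
        shape = np.zeros(n)
        sel = (t >= p.start) & (t < p.end)
        tt = t[sel] - p.start
        dur = p.end - p.start
        s = np.ones_like(tt)
        up = tt < ramp
        s[up] = 0.5 * (1 - np.cos(np.pi * tt[up] / ramp))
        down = tt > dur - ramp
        s[down] = 0.5 * (1 - np.cos(np.pi * (dur - tt[down]) / ramp))
        shape[sel] = amp * s
        i = FINGERS.index(p.finger)
        bursts[muscle, i] = np.maximum(bursts[muscle, i], shape)
        for j in (i - 1, i + 1):
            if 0 <= j < len(FINGERS):
                bursts[muscle, j] = np.maximum(bursts[muscle, j], cfg.crosstalk * shape)
    return np.maximum(BASELINE, bursts)


def draw_subject_params(rng: np.random.Generator, n_fingers: int = 5) -> list[MsmParams]:
    """Per-finger equilibrium-model parameters hitting the protocol angle targets.

    Stiffness and moment-arm constants are drawn from realistic unitless
    ranges; the length constants are then solved so that the equilibrium
    angle is exactly 0 at resting baseline, ``THETA_FLEX_TARGET`` at full
    flexor drive and ``THETA_EXT_TARGET`` at full extensor drive.  Draws
    whose solved lengths violate positivity are rejected and retried.
    """
    eps = BASELINE
    out = []
    for _ in range(n_fingers):
        for _attempt in range(500):
            a1 = rng.uniform(0.8, 1.2)
            a2 = -rng.uniform(0.8, 1.2)
            k0 = np.array([1.0, rng.uniform(0.8, 1.25)])
            k1 = rng.uniform(0.3, 0.7, 2)
            l12 = rng.uniform(0.3, 0.8)
            K1e, K2e = k0 + k1 * eps
            K11 = k0[0] + k1[0]
            K21 = k0[1] + k1[1]
            A = a1 * K1e
            B2e = a2 * K2e
            B21 = a2 * K21
            D_e1 = a1**2 * K1e + a2**2 * K21
            D_1e = a1**2 * K11 + a2**2 * K2e
            l02 = (THETA_EXT_TARGET * D_e1 - l12 * (B21 - B2e * eps)) / (B21 - B2e)
            if l02 <= 0:
                continue
            s0 = -B2e * (l02 + l12 * eps) / A
            s1 = (THETA_FLEX_TARGET * D_1e - B2e * (l02 + l12 * eps)) / (a1 * K11)
            l11 = (s1 - s0) / (1 - eps)
            l01 = s0 - l11 * eps
            if l01 > 0 and l11 > 0:
                out.append(
                    MsmParams(
                        a=np.array([a1, a2]),
                        k0=k0,
                        k1=k1,
                        l0=np.array([l01, l02]),
                        l1=np.array([l11, l12]),
                    )
                )
                break
        else:  # pragma: no cover - rejection sampling exhausts only on a bug
            raise RuntimeError("could not draw positive MSM parameters")
    return out


def _angles_from_activations(activations: np.ndarray, params: list[MsmParams]) -> np.ndarray:
    return np.stack(
        [msm_equilibrium(activations[0, i], activations[1, i], p) for i, p in enumerate(params)]
    )


def _truth_series(
    activations_raw: np.ndarray,
    params: list[MsmParams],
    schedule: PhaseSchedule,
    cfg: SimConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Down-sample activations to FS_TRUTH and derive angles and NRMSD."""
    frac = Fraction(FS_TRUTH / cfg.fs_raw).limit_denominator(10000)
    u = signal.resample_poly(activations_raw, frac.numerator, frac.denominator, axis=2)
    u = np.clip(u, 0.0, 1.0)
    angles = _angles_from_activations(u, params)
    tdir = schedule.tdir_series(FS_TRUTH, angles.shape[1])
    nrmsd = np.zeros_like(angles)
    moving = tdir != 0
    nrmsd[moving] = np.clip(angles[moving] / tdir[moving], 0.0, 1.0)
    return u, angles, nrmsd


# --------------------------------------------------------------------------
# EMG synthesis


def _band_carrier(rng: np.random.Generator, n: int, fs: float, band) -> np.ndarray:
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    return x / np.sqrt(np.mean(x**2))


def source_mixing(layout: ArrayLayout, sigma: float = SOURCE_SIGMA) -> tuple[np.ndarray, dict]:
    """Gaussian-blob mixing matrix (channels × 10) and source locations.

    Sources 0–4 are the per-finger flexors (flexor panel), 5–9 the
    extensors (extensor panel); blob centres sit on the anatomical mask
    blocks, so neighbouring fingers overlap spatially.
    """
    n_src = 2 * len(FINGERS)
    M = np.zeros((len(layout), n_src))
    locations = {}
    for i, finger in enumerate(FINGERS):
        for muscle, side in ((0, FLEXOR), (1, EXTENSOR)):
            s = muscle * len(FINGERS) + i
            r0, c0 = mask_block_center(finger, side)
            locations[s] = {"finger": finger, "side": side, "row": r0, "col": c0}
            for ci, e in enumerate(layout.electrodes):
                if e.side != side:
                    continue
                d2 = (e.row - r0) ** 2 + (e.col - c0) ** 2
                M[ci, s] = np.exp(-d2 / (2 * sigma**2))
    return M, locations


def synthesize_emg(
    activations: np.ndarray,
    schedule: PhaseSchedule,
    layout: ArrayLayout,
    cfg: SimConfig,
    rng_seed: int,
    mixing: np.ndarray | None = None,
    return_parts: bool = False,
):
    """Mix muscle sources onto the array and add interference and noise.

    Each source is its contraction series times an independent unit-RMS
    band-limited carrier; the channel signal is the spatial mixture plus a
    mains sinusoid, white sensor noise scaled so the broadband
    source-to-noise power ratio equals ``cfg.snr_db``, and low-frequency
    (< 5 Hz) motion-artifact bursts during movement phases.
    """
    if mixing is None:
        mixing, _ = source_mixing(layout)
    n_src = 2 * len(FINGERS)
    if mixing.shape != (len(layout), n_src):
        raise ValueError(
            f"mixing shape {mixing.shape} does not match layout "
            f"({len(layout)} channels × {n_src} sources)"
        )
    fs = cfg.fs_raw
    n = int(round(schedule.duration * fs))
    if activations.shape != (2, len(FINGERS), n):
        raise ValueError("activations do not match the schedule duration at fs_raw")
    rng = np.random.default_rng(rng_seed)

    sources = np.empty((n_src, n))
    for m in range(2):
        for i in range(len(FINGERS)):
            carrier = _band_carrier(rng, n, fs, cfg.carrier_band)
            sources[m * len(FINGERS) + i] = activations[m, i] * carrier
    clean = mixing @ sources

    p_signal = float(np.mean(clean**2))
    scale = np.sqrt(p_signal) if p_signal > 0 else 1.0
    t = np.arange(n) / fs

    line_gain = rng.uniform(0.5, 1.5, (len(layout), 1))
    line = 0.2 * scale * line_gain * np.sin(2 * np.pi * cfg.line_freq * t)[None, :]

    noise_sd = np.sqrt(p_signal / 10 ** (cfg.snr_db / 10)) if p_signal > 0 else 0.0
    noise = noise_sd * rng.standard_normal((len(layout), n))

    artifacts = np.zeros((len(layout), n))
    if cfg.artifact_level > 0:
        sos_lo = signal.butter(2, 5.0, btype="lowpass", fs=fs, output="sos")
        for p in schedule.movement_phases():
            sel = (t >= p.start) & (t < p.end)
            burst = signal.sosfilt(sos_lo, rng.standard_normal(int(sel.sum())))
            rms = np.sqrt(np.mean(burst**2))
            if rms > 0:
                burst /= rms
            side_elecs = [e for e in layout.electrodes]
            r0 = rng.uniform(0, 3)
            c0 = rng.uniform(0, 11)
            profile = np.array(
                [np.exp(-((e.row - r0) ** 2 + (e.col - c0) ** 2) / (2 * 2.0**2)) for e in side_elecs]
            )
            artifacts[:, sel] += cfg.artifact_level * scale * np.outer(profile, burst)

    data = clean + line + noise + artifacts
    rec = EmgRecording(
        data=data,
        fs=fs,
        labels=layout.labels,
        trigger=schedule.trigger_code(fs, n),
    )
    if return_parts:
        return rec, {
            "sources": sources,
            "clean": clean,
            "line": line,
            "noise": noise,
            "artifacts": artifacts,
            "mixing": mixing,
        }
    return rec


# --------------------------------------------------------------------------
# datasets


def _make_experiment(
    kind: str,
    finger: str | None,
    cfg: SimConfig,
    layout: ArrayLayout,
    params: list[MsmParams],
    mixing: np.ndarray,
    locations: dict,
    act_seed: int,
    emg_seed: int,
) -> Experiment:
    schedule = generate_protocol(cfg, kind, finger)
    activations = generate_activations(schedule, cfg, act_seed)
    rec = synthesize_emg(activations, schedule, layout, cfg, emg_seed, mixing=mixing)
    u, angles, nrmsd = _truth_series(activations, params, schedule, cfg)
    truth = SimTruth(
        params=params,
        activations=u,
        angles=angles,
        nrmsd=nrmsd,
        fs=FS_TRUTH,
        mixing=mixing,
        source_locations=locations,
    )
    return Experiment(kind=kind, finger=finger, schedule=schedule, recording=rec, truth=truth)


def make_subject(cfg: SimConfig, subject: int, layout: ArrayLayout | None = None) -> SubjectData:
    """Generate one subject: 25 train experiments (5 per finger) + test runs."""
    cfg.validate()
    layout = layout or ArrayLayout.default()
    ss = np.random.SeedSequence([cfg.seed, subject])
    n_exp = len(FINGERS) * cfg.train_exps_per_finger + cfg.test_exps
    children = ss.spawn(1 + 2 * n_exp)
    rng_params = np.random.default_rng(children[0])
    params = draw_subject_params(rng_params)
    mixing, locations = source_mixing(layout)

    def seeds(i):
        a = int(children[1 + 2 * i].generate_state(1)[0] % (2**31))
        b = int(children[2 + 2 * i].generate_state(1)[0] % (2**31))
        return a, b

    train, test = [], []
    i = 0
    for finger in FINGERS:
        for _rep in range(cfg.train_exps_per_finger):
            a, b = seeds(i)
            train.append(
                _make_experiment("train", finger, cfg, layout, params, mixing, locations, a, b)
            )
            i += 1
    for _rep in range(cfg.test_exps):
        a, b = seeds(i)
        test.append(_make_experiment("test", None, cfg, layout, params, mixing, locations, a, b))
        i += 1
    return SubjectData(subject=subject, params=params, train=train, test=test)


def make_dataset(cfg: SimConfig, layout: ArrayLayout | None = None) -> SimDataset:
    """All subjects' experiments, fully reproducible from ``cfg.seed``."""
    cfg.validate()
    layout = layout or ArrayLayout.default()
    subjects = [make_subject(cfg, s, layout) for s in range(cfg.n_subjects)]
    return SimDataset(config=cfg, subjects=subjects)


def iter_subjects(cfg: SimConfig, layout: ArrayLayout | None = None):
    """Lazily generate subjects one at a time (memory-friendly variant)."""
    cfg.validate()
    layout = layout or ArrayLayout.default()
    for s in range(cfg.n_subjects):
        yield make_subject(cfg, s, layout)
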