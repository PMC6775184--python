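"""Ground-truth finger-angle construction from phase triggers.

The instructed protocol alternates 2-s flexion / rest / extension / rest
phases.  The measured quantity is a normalized root-mean-square displacement
(NRMSD) of the finger's joints from a calibration pose, a unitless value in
[0, 1]; the protocol trigger supplies the sign and scale of the motion.  The
finger angle is their composition::

    theta_f(t) = T_dir(t) * NRMSD_f(t)

with T_dir = 2.094 rad during flexion, −0.523 rad during extension and 0 at
rest.  A median filter plus 1-Hz zero-phase low-pass smooths the result.
All angles are in radians; degrees appear only in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .layout import FINGERS

T_FLEXION = 2.094  # rad (= 120 deg)
T_EXTENSION = -0.523  # rad (= -30 deg)
T_REST = 0.0
PHASE_KINDS = ("flexion", "rest", "extension")

_TDIR = {"flexion": T_FLEXION, "extension": T_EXTENSION, "rest": T_REST}


def trigger_value(kind: str) -> float:
    """Protocol direction constant T_dir for a phase kind."""
    return _TDIR[kind]


@dataclass(frozen=True)
class Phase:
    start: float  # s
    end: float  # s
    kind: str  # flexion | rest | extension
    finger: str | None = None  # None for rest / calibration

    def __post_init__(self):
        if self.kind not in PHASE_KINDS:
            raise ValueError(f"unknown phase kind {self.kind!r}")
        if self.end <= self.start:
            raise ValueError("phase duration must be positive")
        if self.kind != "rest" and self.finger not in FINGERS:
            raise ValueError(f"movement phase needs a known finger, got {self.finger!r}")


@dataclass
class PhaseSchedule:
    """Contiguous, non-overlapping protocol phases."""

    phases: list[Phase]

    def __post_init__(self):
        if not self.phases:
            raise ValueError("schedule has no phases")
        for a, b in zip(self.phases, self.phases[1:]):
            if not np.isclose(a.end, b.start):
                raise ValueError("phases must be contiguous and non-overlapping")

    @property
    def start(self) -> float:
        return self.phases[0].start

    @property
    def duration(self) -> float:
        return self.phases[-1].end - self.phases[0].start

    def movement_phases(self) -> list[Phase]:
        return [p for p in self.phases if p.kind != "rest"]

    def phase_at(self, t: float) -> Phase:
        for p in self.phases:
            if p.start <= t < p.end:
                return p
        if np.isclose(t, self.phases[-1].end):
            return self.phases[-1]
        raise ValueError(f"time {t} s outside schedule")

    def tdir_series(self, fs: float, n: int | None = None) -> np.ndarray:
        """Per-finger T_dir series, shape (5, n), sampled at fs."""
        if n is None:
            n = int(round(self.duration * fs))
        t = self.start + np.arange(n) / fs
        if t[-1] > self.phases[-1].end + 0.5 / fs:
            raise ValueError("schedule does not cover the requested time span")
        out = np.zeros((len(FINGERS), n))
        for p in self.phases:
            if p.kind == "rest":
                continue
            i = FINGERS.index(p.finger)
            sel = (t >= p.start) & (t < p.end)
            out[i, sel] = trigger_value(p.kind)
        return out

    def trigger_code(self, fs: float, n: int | None = None) -> np.ndarray:
        """Integer per-sample code: 0 rest, ±(finger_index+1) flexion/extension."""
        if n is None:
            n = int(round(self.duration * fs))
        t = self.start + np.arange(n) / fs
        code = np.zeros(n, dtype=np.int16)
        for p in self.phases:
            if p.kind == "rest":
                continue
            sgn = 1 if p.kind == "flexion" else -1
            sel = (t >= p.start) & (t < p.end)
            code[sel] = sgn * (FINGERS.index(p.finger) + 1)
        return code


@dataclass
class NrmsdSeries:
    """Per-finger normalized RMS displacement in [0, 1], shape (5, n)."""

    values: np.ndarray
    fs: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(FINGERS):
            raise ValueError("values must have shape (5, n_samples)")
        if np.any(self.values < 0) or np.any(self.values > 1 + 1e-9):
            raise ValueError("NRMSD values must lie in [0, 1]")


@dataclass
class FingerTrajectory:
    """Per-finger joint angles theta (rad), shape (5, n)."""

    angles: np.ndarray
    fs: float
    fingers: tuple[str, ...] = field(default=FINGERS)

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2 or self.angles.shape[0] != len(self.fingers):
            raise ValueError("angles must have shape (n_fingers, n_samples)")
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("angles must be finite")
        if np.any(np.abs(self.angles) > np.pi + 1e-9):
            raise ValueError("|theta| must not exceed pi")

    def finger(self, name: str) -> np.ndarray:
        return self.angles[self.fingers.index(name)]


def compute_nrmsd(
    joint_positions: np.ndarray,
    calibration_pose: np.ndarray,
    finger_length: float,
) -> np.ndarray:
    """Normalized RMS joint displacement from the calibration pose.

    Parameters
    ----------
    joint_positions : (n_samples, n_joints, 2) array of 2-D joint coordinates.
    calibration_pose : (n_joints, 2) reference pose, typically the mean pose
        over the experiment's calibration segment.
    finger_length : normalization constant in the same length units.

    Returns the per-sample value
    ``sqrt(mean_j ||p_j(t) − p_j^cal||^2) / finger_length`` clipped to [0, 1].
    """
    if finger_length <= 0:
        raise ValueError("finger_length must be positive")
    pos = np.asarray(joint_positions, dtype=float)
    cal = np.asarray(calibration_pose, dtype=float)
    if pos.ndim != 3 or pos.shape[2] != 2:
        raise ValueError("joint_positions must have shape (n_samples, n_joints, 2)")
    if cal.shape != pos.shape[1:]:
        raise ValueError("calibration pose joint count does not match positions")
    disp2 = np.sum((pos - cal[None]) ** 2, axis=2)  # (n, J)
    nrmsd = np.sqrt(disp2.mean(axis=1)) / finger_length
    return np.clip(nrmsd, 0.0, 1.0)


def finger_angle_from_trigger(nrmsd: NrmsdSeries, schedule: PhaseSchedule) -> FingerTrajectory:
    """Compose trigger direction with displacement: theta = T_dir · NRMSD."""
    n = nrmsd.values.shape[1]
    tdir = schedule.tdir_series(nrmsd.fs, n)
    return FingerTrajectory(angles=tdir * nrmsd.values, fs=nrmsd.fs)


def smooth_trajectory(
    traj: FingerTrajectory,
    lp_cutoff: float = 1.0,
    median_window: float = 0.5,
) -> FingerTrajectory:
    """Median filter (spike rejection) then zero-phase low-pass.

    The median window is given in seconds and rounded to an odd number of
    samples (minimum 3); the low-pass is a 4th-order zero-phase Butterworth.
    """
    win = int(round(median_window * traj.fs))
    if win % 2 == 0:
        win += 1
    if win < 3:
        raise ValueError("median window must span at least 3 samples")
    n = traj.angles.shape[1]
    if win > n:
        raise ValueError("median window larger than the series")
    med = signal.medfilt(traj.angles, kernel_size=(1, win))
    sos = signal.butter(4, lp_cutoff, btype="lowpass", fs=traj.fs, output="sos")
    smoothed = signal.sosfiltfilt(sos, med, axis=1)
    smoothed = np.clip(smoothed, -np.pi, np.pi)
    return FingerTrajectory(angles=smoothed, fs=traj.fs, fingers=traj.fingers)
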