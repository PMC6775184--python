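"""Raw array-EMG conditioning: re-reference, band-pass, resample, envelope.

Pipeline order is fixed — average re-reference → 5–200 Hz band-pass →
polyphase resample to 500 Hz → (ICA happens on the band-limited signals) →
rectified 3-Hz low-pass envelope.  Every filter is zero-phase
(forward–backward 4th-order Butterworth), so envelopes stay time-aligned
with the kinematics — a requirement for correlation-based channel and
component selection.  Channel and component envelopes always use the same
settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal


@dataclass
class EmgRecording:
    """Multichannel EMG block: channels × samples in µV plus metadata."""

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]
    trigger: np.ndarray | None = None  # int code per sample (see PhaseSchedule)
    t0: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels × samples")
        self.labels = tuple(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.trigger is not None:
            self.trigger = np.asarray(self.trigger)
            if self.trigger.shape != (self.data.shape[1],):
                raise ValueError("trigger length must equal sample count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]


@dataclass
class EnvelopeSet:
    """Rectified low-pass amplitudes, one row per signal, values ≥ 0."""

    envelopes: np.ndarray
    fs: float
    source_kind: str  # raw_channel | independent_component
    ids: tuple = ()

    def __post_init__(self):
        self.envelopes = np.asarray(self.envelopes, dtype=float)
        if self.envelopes.ndim != 2:
            raise ValueError("envelopes must be signals × samples")
        if np.any(self.envelopes < 0):
            raise ValueError("envelope values must be non-negative")
        if not self.ids:
            self.ids = tuple(range(self.envelopes.shape[0]))
        if len(self.ids) != self.envelopes.shape[0]:
            raise ValueError("one id per envelope row required")

    def get(self, ident) -> np.ndarray:
        return self.envelopes[self.ids.index(ident)]


def rereference_average(rec: EmgRecording) -> EmgRecording:
    """Subtract the instantaneous across-channel mean (common reference)."""
    if rec.n_channels < 2:
        raise ValueError("average re-reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=data)


def bandpass_filter(rec: EmgRecording, lo: float = 5.0, hi: float = 200.0) -> EmgRecording:
    """Zero-phase 4th-order Butterworth band-pass, per channel."""
    if not (0 < lo < hi < rec.fs / 2):
        raise ValueError(f"band edges must satisfy 0 < {lo} < {hi} < fs/2 = {rec.fs / 2}")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1, padtype="even")
    return replace(rec, data=data)


def resample_signal(rec: EmgRecording, fs_new: float) -> EmgRecording:
    """Anti-aliased polyphase down-sampling; trigger mapped by nearest sample."""
    if fs_new > rec.fs:
        raise ValueError("upsampling is not supported")
    if fs_new == rec.fs:
        return replace(rec)
    frac = Fraction(fs_new / rec.fs).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(rec.data, up, down, axis=1)
    trigger = None
    if rec.trigger is not None:
        idx = np.clip(
            np.round(np.arange(data.shape[1]) * down / up).astype(int),
            0,
            rec.n_samples - 1,
        )
        trigger = rec.trigger[idx]
    return replace(rec, data=data, fs=fs_new, trigger=trigger)


def envelope(
    signals: np.ndarray,
    fs: float,
    cutoff: float = 3.0,
    source_kind: str = "raw_channel",
    ids: tuple = (),
) -> EnvelopeSet:
    """Full-wave rectification then zero-phase 4th-order low-pass.

    Filter ringing can push values slightly negative; those are clamped to 0
    so downstream muscle-contraction inputs satisfy u ≥ 0.
    """
    if cutoff >= fs / 2:
        raise ValueError("envelope cutoff must be below the Nyquist rate")
    x = np.atleast_2d(np.asarray(signals, dtype=float))
    sos = signal.butter(4, cutoff, btype="lowpass", fs=fs, output="sos")
    env = signal.sosfiltfilt(sos, np.abs(x), axis=1, padtype="even")
    env = np.clip(env, 0.0, None)
    return EnvelopeSet(envelopes=env, fs=fs, source_kind=source_kind, ids=ids)


def remove_calibration_offset(env: EnvelopeSet, calibration_end: float) -> EnvelopeSet:
    """Subtract each signal's mean over the initial calibration segment.

    The calibration segment (rest at the start of every experiment) captures
    offset voltage and the noise floor; removing its mean makes rest-level
    envelopes hover near zero.  Negatives are clamped to keep u ≥ 0.
    """
    n_cal = int(round(calibration_end * env.fs))
    if n_cal < 1 or n_cal > env.envelopes.shape[1]:
        raise ValueError("calibration segment outside the recording")
    offset = env.envelopes[:, :n_cal].mean(axis=1, keepdims=True)
    values = np.clip(env.envelopes - offset, 0.0, None)
    return EnvelopeSet(values, env.fs, env.source_kind, env.ids)


def preprocess_pipeline(
    rec: EmgRecording,
    lo: float = 5.0,
    hi: float = 200.0,
    fs_out: float = 500.0,
) -> EmgRecording:
    """Average re-reference → band-pass → resample, in the fixed order."""
    return resample_signal(bandpass_filter(rereference_average(rec), lo, hi), fs_out)
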