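"""File-format adapters: recordings, schedules, tables, parameters, configs.

The writable interchange format for recordings is a delimited table (one
row per sample: time, trigger code, one column per channel, full float
precision so round-trips are bit-identical) plus a JSON sidecar holding the
sampling rate, channel labels and units.  EDF/BDF acquisitions are read
through :mod:`mne`.  Every file written here starts with a provenance
comment line (tool version, seed/config hash where applicable).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kinematics import Phase, PhaseSchedule
from .models import LrmParams, MsmParams
from .preprocess import EmgRecording

FLOAT_FMT = "%.17g"  # lossless float64 text representation


def _provenance_line(**extra) -> str:
    parts = [f"arrayemg {__version__}"] + [f"{k}={v}" for k, v in extra.items()]
    return "# " + " ".join(parts)


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


# --------------------------------------------------------------------------
# recordings


def write_recording(rec: EmgRecording, path, **provenance) -> None:
    """Write ``<path>`` (CSV) and ``<path stem>.json`` sidecar."""
    path = Path(path)
    cols = {"time": rec.t0 + np.arange(rec.n_samples) / rec.fs}
    if rec.trigger is not None:
        cols["TRIG"] = rec.trigger
    for i, lab in enumerate(rec.labels):
        cols[lab] = rec.data[i]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(_provenance_line(**provenance) + "\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)
    sidecar = {
        "fs": rec.fs,
        "t0": rec.t0,
        "labels": list(rec.labels),
        "units": "uV",
        "n_samples": rec.n_samples,
        "has_trigger": rec.trigger is not None,
        "writer": f"arrayemg {__version__}",
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def _read_table_sidecar(path: Path) -> EmgRecording:
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar metadata file {sidecar_path}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    for key in ("fs", "labels"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar_path} lacks required field {key!r}")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    labels = meta["labels"]
    missing = [lab for lab in labels if lab not in df.columns]
    if missing:
        raise ValueError(f"data table lacks channels declared in sidecar: {missing}")
    data = df[labels].to_numpy().T
    trigger = df["TRIG"].to_numpy() if "TRIG" in df.columns else None
    return EmgRecording(
        data=data,
        fs=float(meta["fs"]),
        labels=tuple(labels),
        trigger=trigger,
        t0=float(meta.get("t0", 0.0)),
    )


def _read_edf_bdf(path: Path) -> EmgRecording:
    import mne

    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts → µV
    labels = list(raw.ch_names)
    trigger = None
    for trig_name in ("TRIG", "Status", "STI 014"):
        if trig_name in labels:
            i = labels.index(trig_name)
            trigger = np.round(data[i] / 1e6).astype(int)
            data = np.delete(data, i, axis=0)
            labels.pop(i)
            break
    return EmgRecording(data=data, fs=float(raw.info["sfreq"]), labels=tuple(labels), trigger=trigger)


def read_recording(path, fmt: str = "table_sidecar") -> EmgRecording:
    """Load a recording; ``fmt`` is ``table_sidecar`` or ``edf_bdf``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "table_sidecar":
        return _read_table_sidecar(path)
    if fmt == "edf_bdf":
        return _read_edf_bdf(path)
    raise ValueError(f"unknown recording format {fmt!r}")


# --------------------------------------------------------------------------
# schedules and time-series tables


def write_schedule(schedule: PhaseSchedule, path, **provenance) -> None:
    df = pd.DataFrame(
        [{"start": p.start, "end": p.end, "kind": p.kind, "finger": p.finger or ""}
         for p in schedule.phases]
    )
    with open(path, "w") as fh:
        fh.write(_provenance_line(**provenance) + "\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def read_schedule(path) -> PhaseSchedule:
    df = pd.read_csv(path, comment="#", keep_default_na=False)
    phases = [
        Phase(float(r.start), float(r.end), r.kind, r.finger or None)
        for r in df.itertuples()
    ]
    return PhaseSchedule(phases)


def write_series(values: np.ndarray, fs: float, columns, path, t0: float = 0.0, **provenance) -> None:
    """Time-series table: a ``time`` column (s) plus one column per signal."""
    values = np.atleast_2d(values)
    df = pd.DataFrame({"time": t0 + np.arange(values.shape[1]) / fs})
    for name, row in zip(columns, values):
        df[name] = row
    with open(path, "w") as fh:
        fh.write(_provenance_line(fs=fs, **provenance) + "\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def read_series(path) -> tuple[np.ndarray, float, list[str]]:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "time" not in df.columns:
        raise ValueError(f"{path} lacks a time column")
    t = df["time"].to_numpy()
    if t.size < 2:
        raise ValueError("series too short to infer the sampling rate")
    fs = 1.0 / np.median(np.diff(t))
    cols = [c for c in df.columns if c != "time"]
    return df[cols].to_numpy().T, float(fs), cols


# --------------------------------------------------------------------------
# fitted parameters


def write_params(params, path, **provenance) -> None:
    if isinstance(params, MsmParams):
        doc = {"model": "msm", **params.as_dict()}
    elif isinstance(params, LrmParams):
        doc = {
            "model": "lrm",
            "beta0": params.beta0,
            "beta1": params.beta1,
            "beta2": params.beta2,
            "residual_sd": params.residual_sd,
        }
    else:
        raise TypeError(f"unsupported parameter object {type(params)}")
    doc["provenance"] = {"writer": f"arrayemg {__version__}", **provenance}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_params(path):
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("model") == "msm":
        return MsmParams.from_dict(doc)
    if doc.get("model") == "lrm":
        return LrmParams(doc["beta0"], doc["beta1"], doc["beta2"], doc.get("residual_sd", 0.0))
    raise ValueError(f"{path} does not declare a known model kind")
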