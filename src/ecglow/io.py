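"""Readers and writers for the pipeline's plain-text formats.

Per-night artifacts: ECG as two-column CSV (time_s, mv) at 250 Hz, triaxial
accelerations (time_s, x_g, y_g, z_g), CGM readings (time_s, glucose_mmol_l),
ground-truth beats as JSON.  Numeric round-trips are preserved to better than
1e-9 by writing 12 significant digits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Beat
from .simulate import (FS_HZ, CGMSeries, MorphParams, NightRecording, RawECG,
                       TrueGlucoseTrace, WaveParams)

FLOAT_FMT = "%.12g"


class SchemaError(ValueError):
    """Input file does not conform to the documented schema."""
    exit_code = 3


def write_ecg_csv(ecg: RawECG, path: str | Path) -> None:
    t = ecg.start_time + np.arange(ecg.samples.size) / ecg.fs
    pd.DataFrame({"time_s": t, "mv": ecg.samples}).to_csv(
        path, index=False, float_format=FLOAT_FMT)


def read_ecg_csv(path: str | Path) -> RawECG:
    df = pd.read_csv(path)
    if list(df.columns) != ["time_s", "mv"] or len(df) < 2:
        raise SchemaError(f"{path}: expected columns time_s, mv with >= 2 rows")
    dt = np.diff(df["time_s"].to_numpy())
    fs = 1.0 / np.median(dt)
    if abs(fs - FS_HZ) > 0.5:
        raise SchemaError(f"{path}: 250 Hz required, file implies {fs:.1f} Hz")
    return RawECG(samples=df["mv"].to_numpy(), fs=FS_HZ,
                  start_time=float(df["time_s"].iloc[0]))


def write_accel_csv(accel: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(accel, columns=["time_s", "x_g", "y_g", "z_g"]).to_csv(
        path, index=False, float_format=FLOAT_FMT)


def read_accel_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    if list(df.columns) != ["time_s", "x_g", "y_g", "z_g"]:
        raise SchemaError(f"{path}: expected columns time_s, x_g, y_g, z_g")
    return df.to_numpy(dtype=float)


def write_cgm_csv(cgm: CGMSeries, path: str | Path) -> None:
    pd.DataFrame({"time_s": cgm.timestamps, "glucose_mmol_l": cgm.values}).to_csv(
        path, index=False, float_format=FLOAT_FMT)


def read_cgm_csv(path: str | Path, lag_applied: float = 300.0,
                 strict: bool = False) -> CGMSeries:
    df = pd.read_csv(path)
    if list(df.columns) != ["time_s", "glucose_mmol_l"]:
        raise SchemaError(f"{path}: expected columns time_s, glucose_mmol_l")
    t = df["time_s"].to_numpy(dtype=float)
    v = df["glucose_mmol_l"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        if strict:
            raise SchemaError(f"{path}: timestamps not sorted (strict mode)")
        import warnings
        warnings.warn(f"{path}: CGM timestamps unordered; sorting")
        order = np.argsort(t)
        t, v = t[order], v[order]
    return CGMSeries(timestamps=t, values=v, lag_applied=lag_applied, mard_target=np.nan)


def write_truth_json(night: NightRecording, path: str | Path) -> None:
    payload = {
        "r_times": [float(t) for t in night.truth_r_times],
        "morphs": [{k: dataclasses.asdict(w) for k, w in m.waves().items()}
                   for m in night.truth_morphs],
    }
    Path(path).write_text(json.dumps(payload))


def read_truth_json(path: str | Path) -> tuple[np.ndarray, list[MorphParams]]:
    payload = json.loads(Path(path).read_text())
    morphs = [
        MorphParams(**{k.lower(): WaveParams(**w) for k, w in m.items()})
        for m in payload["morphs"]
    ]
    return np.asarray(payload["r_times"]), morphs


def write_night(night: NightRecording, directory: str | Path, stem: str = "night") -> dict:
    """Write one night's bundle; returns the path map."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "ecg": d / f"{stem}_ecg.csv",
        "accel": d / f"{stem}_accel.csv",
        "cgm": d / f"{stem}_cgm.csv",
        "truth": d / f"{stem}_truth.json",
        "glucose": d / f"{stem}_glucose.csv",
    }
    write_ecg_csv(night.ecg, paths["ecg"])
    write_accel_csv(night.accel, paths["accel"])
    write_cgm_csv(night.cgm, paths["cgm"])
    write_truth_json(night, paths["truth"])
    pd.DataFrame({"time_s": night.true_glucose.timestamps,
                  "glucose_mmol_l": night.true_glucose.values}).to_csv(
        paths["glucose"], index=False, float_format=FLOAT_FMT)
    return {k: str(v) for k, v in paths.items()}


def read_night(directory: str | Path, stem: str = "night") -> NightRecording:
    d = Path(directory)
    ecg = read_ecg_csv(d / f"{stem}_ecg.csv")
    accel = read_accel_csv(d / f"{stem}_accel.csv")
    cgm = read_cgm_csv(d / f"{stem}_cgm.csv")
    g = pd.read_csv(d / f"{stem}_glucose.csv")
    trace = TrueGlucoseTrace(timestamps=g["time_s"].to_numpy(dtype=float),
                             values=g["glucose_mmol_l"].to_numpy(dtype=float))
    r_times, morphs = read_truth_json(d / f"{stem}_truth.json")
    return NightRecording(ecg=ecg, accel=accel, true_glucose=trace, cgm=cgm,
                          truth_r_times=r_times, truth_morphs=morphs)


def write_beat_table(beats: list[Beat], path: str | Path) -> None:
    rows = []
    for b in beats:
        row = {"r_time_s": b.r_time, "activity_g": b.activity, "quality_ok": b.quality_ok}
        row.update({f"s{i:02d}": v for i, v in enumerate(b.series)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def file_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(path: str | Path, **entries) -> None:
    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True, default=str))
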