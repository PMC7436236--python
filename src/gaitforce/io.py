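"""Delimited-text I/O for trials, feature matrices and models.

One trial is a CSV (``time_s``, ``<loc>_<ch>`` for every location/channel,
``vgrf_bw``) plus a JSON sidecar with the metadata; round-trips are lossless
to well below 1e-9.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .synthetic import CHANNELS, LOCATIONS, Trial

__all__ = ["write_trial", "read_trial", "trial_filename",
           "write_features", "read_features"]

_FLOAT_FMT = "%.12g"


def trial_filename(trial: Trial) -> str:
    return f"{trial.subject_id}_speed{trial.speed:.1f}"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trial(trial: Trial, directory, name: str | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = name or trial_filename(trial)
    path = directory / f"{name}.csv"
    cols = {"time_s": np.arange(trial.n_samples) / trial.fs}
    for loc in trial.imu:
        for ci, ch in enumerate(CHANNELS):
            cols[f"{loc}_{ch}"] = trial.imu[loc][ci]
    cols["vgrf_bw"] = trial.vgrf
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {"subject_id": trial.subject_id, "speed": trial.speed,
            "fs": trial.fs, "duration": trial.duration, "mass": trial.mass,
            "seed": trial.seed, "locations": list(trial.imu)}
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_trial(path) -> Trial:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    df = pd.read_csv(path)
    imu = {}
    for loc in meta["locations"]:
        imu[loc] = np.vstack([df[f"{loc}_{ch}"].to_numpy() for ch in CHANNELS])
    trial = Trial(subject_id=meta["subject_id"], speed=meta["speed"],
                  fs=meta["fs"], duration=meta["duration"], mass=meta["mass"],
                  imu=imu, vgrf=df["vgrf_bw"].to_numpy(), seed=meta["seed"])
    trial.validate()
    return trial


def read_trials(directory) -> List[Trial]:
    return [read_trial(p) for p in sorted(Path(directory).glob("*.csv"))]


def write_features(fm: FeatureMatrix, directory, name: str) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{name}.csv"
    df = pd.DataFrame(fm.values, columns=fm.feature_names)
    df["vgrf_bw"] = fm.target
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "location": fm.location, "fs": fm.fs, "window_len": fm.window_len,
        "subject_id": fm.subject_id, "speed": fm.speed,
        "feature_names": fm.feature_names,
        "norm_lo": None if fm.norm_lo is None else list(fm.norm_lo),
        "norm_hi": None if fm.norm_hi is None else list(fm.norm_hi),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_features(path) -> FeatureMatrix:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    df = pd.read_csv(path)
    names = meta["feature_names"]
    return FeatureMatrix(
        values=df[names].to_numpy(),
        feature_names=names,
        location=meta["location"],
        target=df["vgrf_bw"].to_numpy(),
        fs=meta["fs"],
        window_len=meta["window_len"],
        norm_lo=None if meta["norm_lo"] is None else np.asarray(meta["norm_lo"]),
        norm_hi=None if meta["norm_hi"] is None else np.asarray(meta["norm_hi"]),
        subject_id=meta["subject_id"],
        speed=meta["speed"],
    )
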