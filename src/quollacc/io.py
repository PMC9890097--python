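"""Readers/writers for traces, labels, feature tables and configuration.

Traces travel as delimited text with a ``time,x,y,z`` header (the raw-CSV
dialect of Axivity device exports): time either in seconds or as ISO-8601
timestamps (auto-detected), accelerations in g. Samples outside the +/-8 g
device range are clamped with a warning. All tables are plain CSV with
stable headers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .features import G_RANGE, AccelTrace


def read_trace(path, fs: float | None = None) -> AccelTrace:
    """Read and validate a ``time,x,y,z`` trace file.

    The sampling rate is inferred from the first two timestamps unless
    given; uniformity is enforced (the first gap is reported). Out-of-range
    samples are clamped to +/-8 g with a warning.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"{path}: malformed trace file: {exc}") from exc
    required = ["time", "x", "y", "z"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"{path}: expected header time,x,y,z, got {list(df.columns)}")

    time_col = df["time"]
    if pd.api.types.is_numeric_dtype(time_col):
        t = time_col.to_numpy(float)
    else:
        ts = pd.to_datetime(time_col, errors="raise")
        t = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()

    for c in ["x", "y", "z"]:
        if not pd.api.types.is_numeric_dtype(df[c]):
            bad = df[pd.to_numeric(df[c], errors="coerce").isna()].index[0]
            raise ValueError(f"{path}: malformed value in column {c}, line {bad + 2}")
    xyz = df[["x", "y", "z"]].to_numpy(float)
    if np.any(np.abs(xyz) > G_RANGE):
        n_bad = int(np.sum(np.any(np.abs(xyz) > G_RANGE, axis=1)))
        warnings.warn(
            f"{path}: {n_bad} sample(s) outside the +/-{G_RANGE:g} g device "
            "range; clamped", stacklevel=2)
        xyz = np.clip(xyz, -G_RANGE, G_RANGE)

    if fs is None:
        if len(t) < 2:
            raise ValueError(f"{path}: cannot infer sampling rate from <2 samples")
        fs = 1.0 / (t[1] - t[0])
    return AccelTrace(fs=fs, t=t, xyz=xyz)


def write_trace(trace: AccelTrace, path) -> None:
    """Write a trace as ``time,x,y,z`` text, round-trip exact."""
    df = pd.DataFrame({"time": trace.t, "x": trace.xyz[:, 0],
                       "y": trace.xyz[:, 1], "z": trace.xyz[:, 2]})
    df.to_csv(path, index=False, float_format="%.17g")


def write_labels(labels, path, epoch_s: float = 1.0) -> None:
    """Write per-epoch labels as ``epoch_start,behavior``."""
    labels = np.asarray(labels, dtype=object)
    pd.DataFrame({"epoch_start": np.arange(len(labels)) * epoch_s,
                  "behavior": labels}).to_csv(path, index=False)


def read_labels(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df["behavior"].to_numpy(object)


def write_features(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=False, float_format="%.17g")


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end pipeline run."""

    fs: float = 50.0
    epoch_s: float = 1.0
    grid_shape: tuple[int, int] = (7, 10)
    train_fraction: float = 0.8
    min_rest_minutes: float = 10.0
    duration_h: float = 6.0
    seed: int = 0
    n_perm: int = 499
    sexes: tuple[str, ...] = ("male", "female")
    timezone_hour_offset: float = 0.0

    def __post_init__(self):
        for name in ("fs", "epoch_s", "train_fraction", "min_rest_minutes",
                     "duration_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.grid_shape[0] < 1 or self.grid_shape[1] < 1:
            raise ValueError("grid dimensions must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "grid_shape" in doc:
            doc["grid_shape"] = tuple(doc["grid_shape"])
        if "sexes" in doc:
            doc["sexes"] = tuple(doc["sexes"])
        return cls(**doc)

    def to_dict(self) -> dict:
        return {
            "fs": self.fs, "epoch_s": self.epoch_s,
            "grid_shape": list(self.grid_shape),
            "train_fraction": self.train_fraction,
            "min_rest_minutes": self.min_rest_minutes,
            "duration_h": self.duration_h, "seed": self.seed,
            "n_perm": self.n_perm, "sexes": list(self.sexes),
            "timezone_hour_offset": self.timezone_hour_offset,
        }
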