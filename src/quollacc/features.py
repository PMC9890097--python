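"""Epoch segmentation and per-epoch predictor extraction.

Traces are cut into non-overlapping 1-s epochs and each epoch is reduced to
25 predictors spanning seven families: per-axis means, standard errors,
standard deviations, skews, minima, maxima, signal magnitude area (SMA),
overall body acceleration (OBA), vectorial body acceleration (VBA, mean and
1-s maximum) and pairwise axis correlations.

VBA is the Euclidean norm of the *raw* sample — it keeps the static 1 g of
gravity, so it sits at ~1 g for a motionless animal and grows with dynamic
movement; VBAmax (the maximum over the 1-s window) is the energy proxy used
throughout the energetics analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Column order of the 25 per-epoch predictors.
FEATURE_COLUMNS: tuple[str, ...] = (
    "mean_x", "mean_y", "mean_z",
    "se_x", "se_y", "se_z",
    "sd_x", "sd_y", "sd_z",
    "skew_x", "skew_y", "skew_z",
    "min_x", "min_y", "min_z",
    "max_x", "max_y", "max_z",
    "sma", "oba_mean", "vba_mean", "vba_max",
    "corr_xy", "corr_xz", "corr_yz",
)

#: Device g-range; samples beyond this saturate the sensor.
G_RANGE = 8.0


@dataclass
class AccelTrace:
    """A uniformly sampled tri-axial acceleration trace in g.

    ``t`` is seconds from trace start; ``xyz`` has one row per sample
    (columns x, y, z — posterior, right-lateral, ventral in the deployment
    convention); ``labels`` optionally carries one behaviour per 1-s epoch.
    """

    fs: float
    t: np.ndarray
    xyz: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n_samples, 3)")
        if len(self.t) != len(self.xyz):
            raise ValueError("t and xyz lengths differ")
        check_uniform(self.t, self.fs)

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def check_uniform(t: np.ndarray, fs: float, rtol: float = 1e-3) -> None:
    """Reject a timestamp vector that is not uniform at 1/fs, reporting the
    first offending gap."""
    if len(t) < 2:
        return
    dt = np.diff(t)
    bad = np.flatnonzero(np.abs(dt - 1.0 / fs) > rtol / fs)
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"non-uniform timestamps: gap of {dt[i]:.6g} s between samples "
            f"{i} and {i + 1} (expected {1.0 / fs:.6g} s)")


def vba(sample) -> float:
    """Vectorial body acceleration: Euclidean norm of the raw sample (g).

    Gravity is deliberately *not* removed, so a motionless device reads
    1 g regardless of orientation.
    """
    s = np.asarray(sample, dtype=float)
    return float(np.sqrt(np.sum(s * s, axis=-1)))


def oba(sample) -> float:
    """Overall body acceleration: sum of absolute raw axis values (g)."""
    s = np.asarray(sample, dtype=float)
    return float(np.sum(np.abs(s), axis=-1))


def sma(epoch) -> float:
    """Signal magnitude area: epoch mean of per-sample |x|+|y|+|z| (g)."""
    e = np.asarray(epoch, dtype=float)
    if e.size == 0:
        raise ValueError("sma of an empty epoch is undefined")
    return float(np.mean(np.sum(np.abs(e), axis=1)))


def epoch_split(trace: AccelTrace, epoch_s: float = 1.0) -> np.ndarray:
    """Cut a trace into non-overlapping epochs aligned to the trace start.

    Returns an array of shape ``(n_epochs, fs*epoch_s, 3)``; a trailing
    partial window is discarded.
    """
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")
    spe = int(round(trace.fs * epoch_s))
    n_epochs = trace.n_samples // spe
    return trace.xyz[: n_epochs * spe].reshape(n_epochs, spe, 3)


def epochs_to_hours(n_epochs: int, epoch_s: float = 1.0) -> float:
    """Convert an epoch count to hours of data."""
    return n_epochs * epoch_s / 3600.0


def _skew(a: np.ndarray) -> float:
    # bias-adjusted sample skewness; 0 by convention on a constant axis
    if np.ptp(a) == 0:
        return 0.0
    return float(stats.skew(a, bias=False))


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    # Pearson within the epoch; 0 by convention if either axis is constant
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def extract_features(epoch) -> dict[str, float]:
    """Compute the 25 predictors for one epoch (array of shape (n, 3))."""
    e = np.asarray(epoch, dtype=float)
    if e.ndim != 2 or e.shape[1] != 3:
        raise ValueError("epoch must have shape (n_samples, 3)")
    n = len(e)
    if n < 2:
        raise ValueError("an epoch needs at least 2 samples")

    mean = e.mean(axis=0)
    sd = e.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    norms = np.linalg.norm(e, axis=1)

    out: dict[str, float] = {}
    for i, ax in enumerate("xyz"):
        out[f"mean_{ax}"] = float(mean[i])
        out[f"se_{ax}"] = float(se[i])
        out[f"sd_{ax}"] = float(sd[i])
        out[f"skew_{ax}"] = _skew(e[:, i])
        out[f"min_{ax}"] = float(e[:, i].min())
        out[f"max_{ax}"] = float(e[:, i].max())
    out["sma"] = sma(e)
    out["oba_mean"] = float(np.mean(np.sum(np.abs(e), axis=1)))
    out["vba_mean"] = float(norms.mean())
    out["vba_max"] = float(norms.max())
    out["corr_xy"] = _corr(e[:, 0], e[:, 1])
    out["corr_xz"] = _corr(e[:, 0], e[:, 2])
    out["corr_yz"] = _corr(e[:, 1], e[:, 2])
    return out


def features_block(epochs: np.ndarray) -> pd.DataFrame:
    """Vectorized 25-predictor table for a stack of epochs (N, n, 3).

    Computes the same quantities as :func:`extract_features` applied
    per epoch (the two paths are cross-checked in the test suite).
    """
    e = np.asarray(epochs, dtype=float)
    if e.ndim != 3 or e.shape[2] != 3 or e.shape[1] < 2:
        raise ValueError("epochs must have shape (N, n>=2, 3)")
    n = e.shape[1]
    mean = e.mean(axis=1)
    sd = e.std(axis=1, ddof=1)
    se = sd / np.sqrt(n)
    constant = np.ptp(e, axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        warnings.simplefilter("ignore")
        skew = stats.skew(e, axis=1, bias=False)
    skew = np.where(constant, 0.0, skew)
    norms = np.linalg.norm(e, axis=2)
    abssum = np.abs(e).sum(axis=2)

    centered = e - mean[:, None, :]
    def corr(i, j):
        cov = (centered[:, :, i] * centered[:, :, j]).sum(axis=1) / (n - 1)
        denom = sd[:, i] * sd[:, j]
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(denom > 0, cov / denom, 0.0)
        return np.clip(c, -1.0, 1.0)

    cols = {}
    for i, ax in enumerate("xyz"):
        cols[f"mean_{ax}"] = mean[:, i]
        cols[f"se_{ax}"] = se[:, i]
        cols[f"sd_{ax}"] = sd[:, i]
        cols[f"skew_{ax}"] = skew[:, i]
        cols[f"min_{ax}"] = e[:, :, i].min(axis=1)
        cols[f"max_{ax}"] = e[:, :, i].max(axis=1)
    cols["sma"] = abssum.mean(axis=1)
    cols["oba_mean"] = abssum.mean(axis=1)
    cols["vba_mean"] = norms.mean(axis=1)
    cols["vba_max"] = norms.max(axis=1)
    cols["corr_xy"] = corr(0, 1)
    cols["corr_xz"] = corr(0, 2)
    cols["corr_yz"] = corr(1, 2)
    return pd.DataFrame(cols, columns=list(FEATURE_COLUMNS))


def compute_features(trace: AccelTrace, epoch_s: float = 1.0,
                     start_hour: float = 0.0) -> pd.DataFrame:
    """Feature table for a whole trace: one row per epoch.

    Columns: ``epoch_s`` (epoch start, seconds), ``hour`` (clock hour of the
    epoch given the trace's start hour), the 25 predictors, and ``behavior``
    if the trace carries labels.
    """
    epochs = epoch_split(trace, epoch_s)
    df = features_block(epochs)
    starts = np.arange(len(epochs)) * epoch_s
    df.insert(0, "epoch_s", starts)
    df.insert(1, "hour", ((start_hour + starts / 3600.0) % 24).astype(int))
    if trace.labels is not None:
        df["behavior"] = np.asarray(trace.labels[: len(epochs)], dtype=object)
    return df
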