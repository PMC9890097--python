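"""Locomotor bouts, the VBA→speed model, and distance accumulation.

Continuous locomotor bouts — maximal runs of consecutive 1-s epochs sharing
one gait label — are extracted from the classifier's predictions; the mean
vectorial body acceleration (VBA) over a bout predicts its mean speed
through a per-gait linear model on the log10–log10 scale,

    log10(speed m/s) = a_k + b_k * log10(mean VBA g),

fitted to calibration bouts (gait-specific intercept and slope, i.e. the
full gait x log10(VBA) interaction). Distance is speed times duration,
accumulated per individual and day.

Galloping carries no calibration coefficients of its own: its beat pattern
resembles a walk (3–4 beats, unlike the 2-beat bound), so gallop bouts are
predicted with the Walking coefficients by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .vocabulary import LOCOMOTOR

#: Gaits predicted with another gait's coefficients.
DEFAULT_GAIT_ALIASES: dict[str, str] = {"Galloping": "Walking"}


def extract_bouts(labels, target_classes=LOCOMOTOR, epoch_vba=None,
                  epoch_s: float = 1.0) -> pd.DataFrame:
    """Maximal runs of identical target-class labels.

    Returns one row per bout with ``behavior``, ``start_s``, ``duration_s``
    and, when per-epoch VBA values are supplied, ``mean_vba`` over the
    bout's epochs. A label change of any kind — including between two
    target classes — ends a bout.
    """
    labels = np.asarray(labels, dtype=object)
    targets = set(target_classes)
    rows = []
    n = len(labels)
    i = 0
    while i < n:
        lab = labels[i]
        j = i + 1
        while j < n and labels[j] == lab:
            j += 1
        if lab in targets:
            row = {
                "behavior": lab,
                "start_s": i * epoch_s,
                "duration_s": (j - i) * epoch_s,
            }
            if epoch_vba is not None:
                row["mean_vba"] = float(np.mean(np.asarray(epoch_vba)[i:j]))
            rows.append(row)
        i = j
    cols = ["behavior", "start_s", "duration_s"] + (
        ["mean_vba"] if epoch_vba is not None else [])
    return pd.DataFrame(rows, columns=cols)


@dataclass
class SpeedModel:
    """Per-gait coefficients of the log10 VBA -> log10 speed regression."""

    coef: dict[str, tuple[float, float]]      # gait -> (intercept, slope)
    se: dict[str, tuple[float, float]]        # standard errors, same layout
    r_squared: float
    residual_var: float
    gait_aliases: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_GAIT_ALIASES))

    def resolve(self, gait: str) -> str:
        g = self.gait_aliases.get(gait, gait)
        if g not in self.coef:
            raise ValueError(f"no speed coefficients for gait {gait!r}")
        return g

    def save(self, path) -> None:
        doc = {
            "format": "quollacc-speedmodel", "version": 1,
            "coef": {k: list(v) for k, v in self.coef.items()},
            "se": {k: list(v) for k, v in self.se.items()},
            "r_squared": self.r_squared,
            "residual_var": self.residual_var,
            "gait_aliases": self.gait_aliases,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "SpeedModel":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "quollacc-speedmodel":
            raise ValueError(f"{path}: not a quollacc speed-model file")
        return cls(
            coef={k: tuple(v) for k, v in doc["coef"].items()},
            se={k: tuple(v) for k, v in doc["se"].items()},
            r_squared=doc["r_squared"], residual_var=doc["residual_var"],
            gait_aliases=dict(doc["gait_aliases"]))


def fit_speed_model(calibration: pd.DataFrame,
                    gait_aliases: dict[str, str] | None = None) -> SpeedModel:
    """OLS of log10 speed on log10 mean VBA with gait-specific intercept and
    slope (full interaction, fitted per gait).

    ``calibration`` needs columns ``gait``, ``mean_vba``, ``speed``; every
    speed and VBA must be positive, and each gait needs at least 3 bouts.
    """
    df = calibration
    bad = np.flatnonzero((df["speed"] <= 0) | (df["mean_vba"] <= 0))
    if bad.size:
        raise ValueError(
            f"non-positive speed or mean_vba at calibration row {int(bad[0])}")

    coef, se = {}, {}
    resid_ss = 0.0
    total_ss = 0.0
    n_total = 0
    y_all = np.log10(df["speed"].to_numpy())
    y_mean = y_all.mean()
    for gait, sub in df.groupby("gait", sort=True):
        if len(sub) < 3:
            raise ValueError(f"gait {gait!r} has {len(sub)} bouts; need >= 3")
        x = np.log10(sub["mean_vba"].to_numpy())
        y = np.log10(sub["speed"].to_numpy())
        res = sm.OLS(y, sm.add_constant(x)).fit()
        coef[gait] = (float(res.params[0]), float(res.params[1]))
        se[gait] = (float(res.bse[0]), float(res.bse[1]))
        resid_ss += float(res.ssr)
        total_ss += float(((y - y_mean) ** 2).sum())
        n_total += len(sub)

    r2 = 1.0 - resid_ss / total_ss if total_ss > 0 else 1.0
    dof = n_total - 2 * len(coef)
    resid_var = resid_ss / dof if dof > 0 else 0.0
    return SpeedModel(coef=coef, se=se, r_squared=r2, residual_var=resid_var,
                      gait_aliases=dict(DEFAULT_GAIT_ALIASES)
                      if gait_aliases is None else dict(gait_aliases))


def predict_speed(model: SpeedModel, gait: str, mean_vba) -> np.ndarray | float:
    """Predicted bout speed in m/s: ``10**(a_k + b_k * log10(mean_vba))``."""
    v = np.asarray(mean_vba, dtype=float)
    if np.any(v <= 0):
        raise ValueError("mean_vba must be positive")
    a, b = model.coef[model.resolve(gait)]
    out = 10.0 ** (a + b * np.log10(v))
    return float(out) if out.ndim == 0 else out


def predict_bout_speeds(model: SpeedModel, bouts: pd.DataFrame) -> pd.DataFrame:
    """Add ``speed_ms`` and ``distance_m`` columns to a bout table."""
    out = bouts.copy()
    speeds = np.array([
        predict_speed(model, row.behavior, row.mean_vba)
        for row in bouts.itertuples()])
    out["speed_ms"] = speeds
    out["distance_m"] = out["speed_ms"] * out["duration_s"]
    return out


def bout_distance(speed_ms: float, duration_s: float) -> float:
    """Distance of one bout in metres: average speed times duration."""
    if duration_s <= 0:
        raise ValueError("bout duration must be positive")
    return speed_ms * duration_s


def daily_distance(bouts: pd.DataFrame, individual_col: str = "individual",
                   day_col: str | None = None) -> pd.DataFrame:
    """Total distance per individual and day, in km.

    Bouts carry ``start_s``, ``distance_m`` and an individual column; the
    day is taken from ``day_col`` if given, else derived from the bout's
    *start* time (bouts crossing midnight count toward the day they start).
    """
    df = bouts.copy()
    if individual_col not in df.columns:
        df[individual_col] = "all"
    if day_col is None:
        df["day"] = (df["start_s"] // 86400).astype(int)
        day_col = "day"
    out = (df.groupby([individual_col, day_col], sort=True)["distance_m"]
           .sum().rename("distance_km") / 1000.0)
    return out.reset_index()
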