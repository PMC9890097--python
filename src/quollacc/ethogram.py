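"""Activity budgets, hour-of-day profiles and VBAmax aggregation.

The ethogram summaries answer "what does the animal do, and when": the
percentage of epochs spent in each behaviour (overall or within groups such
as sex or individual), the same budget resolved by local clock hour
[h, h+1), a low/medium/high energy-class grouping keyed on typical per-epoch
peak VBA, and grouped means of VBAmax as the diel energy-expenditure
profile.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .vocabulary import BEHAVIORS, DEFAULT_ENERGY_CLASS, validate_labels


def activity_budget(labels, groups=None, classes=BEHAVIORS) -> pd.DataFrame:
    """Percentage of epochs per behaviour; rows sum to 100 within a group.

    Without ``groups`` returns a single-row table (index ``'overall'``);
    with a group vector (sex, individual, ...) one row per group. Groups
    with no epochs are omitted with a warning.
    """
    labels = np.asarray(labels, dtype=object)
    validate_labels(pd.unique(labels))
    if groups is None:
        groups = np.repeat("overall", len(labels))
    groups = np.asarray(groups, dtype=object)
    if len(groups) != len(labels):
        raise ValueError("labels and groups lengths differ")

    out = {}
    for g in pd.unique(groups):
        mask = groups == g
        if not mask.any():
            warnings.warn(f"group {g!r} has no epochs; omitted", stacklevel=2)
            continue
        counts = pd.Series(labels[mask]).value_counts()
        out[g] = [100.0 * counts.get(c, 0) / mask.sum() for c in classes]
    return pd.DataFrame.from_dict(out, orient="index", columns=list(classes))


def hourly_profile(labels, hours, classes=BEHAVIORS) -> pd.DataFrame:
    """Budget per local clock hour: 24 rows, each summing to 100.

    Hours with no epochs are kept as all-NaN rows so the gap is visible.
    """
    labels = np.asarray(labels, dtype=object)
    hours = np.asarray(hours, dtype=int)
    if np.any((hours < 0) | (hours > 23)):
        raise ValueError("hours must lie in 0..23")
    prof = pd.DataFrame(np.nan, index=range(24), columns=list(classes))
    for h in range(24):
        mask = hours == h
        if mask.any():
            counts = pd.Series(labels[mask]).value_counts()
            prof.loc[h] = [100.0 * counts.get(c, 0) / mask.sum() for c in classes]
    prof.index.name = "hour"
    return prof


def energy_class(behavior: str, mapping: dict[str, str] | None = None) -> str:
    """Low/medium/high energy class of a behaviour."""
    mapping = DEFAULT_ENERGY_CLASS if mapping is None else mapping
    if behavior not in mapping:
        raise ValueError(f"behaviour not in energy-class map: {behavior!r}")
    return mapping[behavior]


def energy_budget(labels, mapping: dict[str, str] | None = None) -> pd.Series:
    """Percentage of epochs in each energy class."""
    labels = np.asarray(labels, dtype=object)
    classes = pd.Series([energy_class(l, mapping) for l in labels])
    return 100.0 * classes.value_counts() / len(labels)


def vba_max_aggregate(features: pd.DataFrame, by: str = "hour") -> pd.DataFrame:
    """Mean and dispersion of per-epoch VBAmax per group.

    ``by`` names a grouping column already present in the feature table
    (``hour``, ``day``, ``individual``, ...). Deterministic group-by.
    """
    if by not in features.columns:
        raise ValueError(f"feature table has no column {by!r}")
    if "vba_max" not in features.columns:
        raise ValueError("feature table has no vba_max column")
    g = features.groupby(by, sort=True)["vba_max"]
    out = g.agg(mean="mean", sd="std", n="count")
    out["sd"] = out["sd"].fillna(0.0)  # single-epoch groups have no spread
    return out


def plot_hourly_profile(profile: pd.DataFrame, path=None):
    """Stacked-area chart of the hourly behaviour profile."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    filled = profile.fillna(0.0)
    ax.stackplot(filled.index, filled.T.to_numpy(), labels=filled.columns)
    ax.set_xlabel("hour of day")
    ax.set_ylabel("% of epochs")
    ax.set_xlim(0, 23)
    ax.legend(fontsize=6, ncol=2, loc="upper left")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
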