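"""Confusion-matrix construction and one-vs-rest accuracy measures.

For each behaviour the classifier is scored as a binary detector:
sensitivity TP/(TP+FN), precision TP/(TP+FP), specificity TN/(TN+FP) and
accuracy (TP+TN)/total. A 0/0 ratio (e.g. sensitivity of a class absent
from the truth) is reported as ``None`` — an explicit undefined marker —
rather than silently zero or NaN. A separate global multiclass accuracy
(diagonal sum over total) is also provided.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .vocabulary import BEHAVIORS


def confusion(true_labels, pred_labels, classes=BEHAVIORS) -> pd.DataFrame:
    """Counts matrix with rows = true class, columns = predicted class."""
    t = np.asarray(true_labels, dtype=object)
    p = np.asarray(pred_labels, dtype=object)
    if len(t) != len(p):
        raise ValueError("true and predicted label lengths differ")
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for ti, pi in zip(t, p):
        if ti not in index:
            raise ValueError(f"unknown true label: {ti!r}")
        if pi not in index:
            raise ValueError(f"unknown predicted label: {pi!r}")
        counts[index[ti], index[pi]] += 1
    return pd.DataFrame(counts, index=classes, columns=classes)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def class_metrics(cm: pd.DataFrame, cls: str) -> dict[str, float | None]:
    """One-vs-rest sensitivity, precision, specificity and accuracy."""
    if cls not in cm.index:
        raise ValueError(f"class not in confusion matrix: {cls!r}")
    total = int(cm.to_numpy().sum())
    tp = int(cm.loc[cls, cls])
    fn = int(cm.loc[cls].sum()) - tp
    fp = int(cm[cls].sum()) - tp
    tn = total - tp - fn - fp
    return {
        "sensitivity": _ratio(tp, tp + fn),
        "precision": _ratio(tp, tp + fp),
        "specificity": _ratio(tn, tn + fp),
        "accuracy": _ratio(tp + tn, total),
    }


def metrics_table(cm: pd.DataFrame) -> pd.DataFrame:
    """Per-behaviour metric table (behaviour x metric), undefined as NaN."""
    rows = {cls: class_metrics(cm, cls) for cls in cm.index}
    return pd.DataFrame.from_dict(rows, orient="index").astype(float)


def overall_accuracy(cm: pd.DataFrame) -> float | None:
    """Global multiclass accuracy: diagonal sum / grand total."""
    total = int(cm.to_numpy().sum())
    return _ratio(int(np.trace(cm.to_numpy())), total)
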