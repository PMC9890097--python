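"""Supervised Self-organizing-Map behaviour classifier.

A Kohonen SOM is a rectangular grid of codebook vectors trained by
competitive updates: at each step the best-matching unit (BMU, the node
nearest the presented vector in Euclidean distance) and its grid
neighbourhood move toward the vector, with learning rate and neighbourhood
radius decaying over training. Classification is supervised post hoc: each
node is labelled by majority vote of the training epochs it wins, and new
epochs take the label of their BMU.

Features are z-scored with training-set statistics only; zero-variance
features are dropped (with a warning) rather than dividing by zero. The
grid defaults to 7 x 10, the shape used for the quoll ethogram.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .features import FEATURE_COLUMNS

DEFAULT_GRID = (7, 10)


@dataclass(frozen=True)
class TrainTestSplit:
    """Holdout specification: default 80% train / 20% test, stratified."""

    train_fraction: float = 0.8
    stratify: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def split_data(features: pd.DataFrame, labels, spec: TrainTestSplit = TrainTestSplit()):
    """Partition epochs into train/test sets (disjoint, exhaustive, seeded).

    With stratification every behaviour class is split close to the
    requested fraction; a class with fewer than 2 epochs cannot appear on
    both sides and is rejected by name.
    """
    labels = np.asarray(labels, dtype=object)
    if len(features) != len(labels):
        raise ValueError("features and labels lengths differ")
    if spec.stratify:
        counts = Counter(labels)
        for cls, c in counts.items():
            if c < 2:
                raise ValueError(
                    f"behaviour class {cls!r} has only {c} epoch(s); "
                    "need at least 2 for a stratified split")
    idx = np.arange(len(labels))
    tr, te = train_test_split(
        idx, train_size=spec.train_fraction,
        stratify=labels if spec.stratify else None,
        random_state=spec.seed, shuffle=True)
    tr, te = np.sort(tr), np.sort(te)
    return (features.iloc[tr], labels[tr]), (features.iloc[te], labels[te])


@dataclass
class SOMModel:
    """A trained (optionally labelled) SOM."""

    grid_shape: tuple[int, int]
    codebook: np.ndarray               # (n_nodes, n_kept_features)
    feature_names: list[str]           # all input feature names, in order
    kept: np.ndarray                   # indices of features kept (sd > 0)
    feature_means: np.ndarray          # over kept features, training set
    feature_sds: np.ndarray
    seed: int
    hyperparams: dict = field(default_factory=dict)
    node_labels: list[str] | None = None
    quantization_error: float | None = None
    initial_codebook: np.ndarray | None = None      # not serialized
    initial_quantization_error: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def zscore(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] == len(self.feature_names):
            X = X[:, self.kept]
        elif X.shape[1] != len(self.kept):
            raise ValueError(
                f"feature dimension {X.shape[1]} matches neither the input "
                f"({len(self.feature_names)}) nor kept ({len(self.kept)}) size")
        return (X - self.feature_means) / self.feature_sds

    # ---- serialization (versioned JSON container) ----

    def save(self, path) -> None:
        doc = {
            "format": "quollacc-som", "version": 1,
            "grid_shape": list(self.grid_shape),
            "codebook": self.codebook.tolist(),
            "feature_names": self.feature_names,
            "kept": self.kept.tolist(),
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "seed": self.seed,
            "hyperparams": self.hyperparams,
            "node_labels": self.node_labels,
            "quantization_error": self.quantization_error,
            "initial_quantization_error": self.initial_quantization_error,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "SOMModel":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "quollacc-som":
            raise ValueError(f"{path}: not a quollacc SOM model file")
        return cls(
            grid_shape=tuple(doc["grid_shape"]),
            codebook=np.asarray(doc["codebook"], dtype=float),
            feature_names=list(doc["feature_names"]),
            kept=np.asarray(doc["kept"], dtype=int),
            feature_means=np.asarray(doc["feature_means"], dtype=float),
            feature_sds=np.asarray(doc["feature_sds"], dtype=float),
            seed=int(doc["seed"]),
            hyperparams=dict(doc["hyperparams"]),
            node_labels=doc["node_labels"],
            quantization_error=doc["quantization_error"],
            initial_quantization_error=doc.get("initial_quantization_error"),
        )


def _as_matrix(features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        cols = [c for c in FEATURE_COLUMNS if c in features.columns]
        if len(cols) == len(FEATURE_COLUMNS):
            return features[list(FEATURE_COLUMNS)].to_numpy(float), list(FEATURE_COLUMNS)
        num = features.select_dtypes("number")
        return num.to_numpy(float), list(num.columns)
    X = np.asarray(features, dtype=float)
    return X, [f"f{i}" for i in range(X.shape[1])]


def _grid_coords(shape: tuple[int, int]) -> np.ndarray:
    r, c = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return np.column_stack([r.ravel(), c.ravel()]).astype(float)


def train_som(features, grid_shape: tuple[int, int] = DEFAULT_GRID,
              n_iter: int | None = None,
              lr: tuple[float, float] = (0.5, 0.01),
              radius: tuple[float, float] | None = None,
              seed: int = 0) -> SOMModel:
    """Train an unlabelled SOM by online Kohonen updates.

    At step ``t`` a random training vector ``x`` is presented, its BMU ``b``
    found, and every node ``w`` moved by ``lr(t) * h(w, b, t) * (x - w)``
    with a Gaussian neighbourhood ``h`` over grid coordinates. Learning rate
    and radius decay linearly from their initial to final values. The
    codebook starts from seeded standard-normal noise in z-scored space.
    """
    X, names = _as_matrix(features)
    if not np.all(np.isfinite(X)):
        bad = int(np.flatnonzero(~np.isfinite(X).all(axis=1))[0])
        raise ValueError(f"non-finite feature values at row {bad}")
    n, d = X.shape
    n_nodes = grid_shape[0] * grid_shape[1]
    if n < n_nodes:
        warnings.warn(
            f"only {n} training rows for {n_nodes} nodes; the map will be "
            "under-determined", stacklevel=2)

    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    kept = np.flatnonzero(sds > 0)
    if len(kept) < d:
        dropped = [names[i] for i in range(d) if i not in set(kept)]
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
    Z = (X[:, kept] - means[kept]) / sds[kept]

    if n_iter is None:
        n_iter = int(np.clip(10 * n, 2000, 30000))
    if radius is None:
        radius = (max(grid_shape) / 2.0, 0.5)

    rng = np.random.default_rng(seed)
    codebook = rng.standard_normal((n_nodes, len(kept))) * 0.5
    coords = _grid_coords(grid_shape)

    model = SOMModel(
        grid_shape=tuple(grid_shape), codebook=codebook,
        feature_names=names, kept=kept,
        feature_means=means[kept], feature_sds=sds[kept], seed=seed,
        hyperparams={"n_iter": n_iter, "lr": list(lr), "radius": list(radius)},
        initial_codebook=codebook.copy())
    model.initial_quantization_error = _qe(codebook, Z)
    codebook = codebook.copy()

    order = rng.integers(0, n, size=n_iter)
    for t, i in enumerate(order):
        frac = t / max(1, n_iter - 1)
        a = lr[0] + (lr[1] - lr[0]) * frac
        sigma = radius[0] + (radius[1] - radius[0]) * frac
        x = Z[i]
        diffs = codebook - x
        b = int(np.argmin(np.einsum("ij,ij->i", diffs, diffs)))
        g2 = np.sum((coords - coords[b]) ** 2, axis=1)
        h = np.exp(-g2 / (2.0 * sigma * sigma))
        codebook -= (a * h)[:, None] * diffs

    model.codebook = codebook
    model.quantization_error = _qe(codebook, Z)
    return model


def _qe(codebook: np.ndarray, Z: np.ndarray) -> float:
    d2 = (Z * Z).sum(axis=1)[:, None] - 2 * Z @ codebook.T \
        + (codebook * codebook).sum(axis=1)[None, :]
    return float(np.sqrt(np.maximum(d2.min(axis=1), 0.0)).mean())


def quantization_error(model: SOMModel, features) -> float:
    """Mean Euclidean distance of each (z-scored) vector to its BMU."""
    X, _ = _as_matrix(features)
    return _qe(model.codebook, model.zscore(X))


def bmu(model: SOMModel, vector) -> int:
    """Best-matching unit of one feature vector (ties -> lowest index)."""
    return int(bmu_batch(model, np.atleast_2d(np.asarray(vector, dtype=float)))[0])


def bmu_batch(model: SOMModel, features) -> np.ndarray:
    """BMU indices for many vectors; exact argmin over all nodes."""
    X, _ = _as_matrix(features)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    Z = model.zscore(X)
    # (n, nodes) squared distances; np.argmin returns the lowest index on ties
    d2 = (Z * Z).sum(axis=1)[:, None] - 2 * Z @ model.codebook.T \
        + (model.codebook * model.codebook).sum(axis=1)[None, :]
    return np.argmin(d2, axis=1)


def label_nodes(model: SOMModel, train_features, train_labels) -> SOMModel:
    """Label every node by majority vote of the training epochs it wins.

    Vote ties break toward the class most frequent in the whole training
    set, then lexicographically. Nodes that win no epochs inherit the label
    of the nearest labelled node in codebook (Euclidean) space.
    """
    labels = np.asarray(train_labels, dtype=object)
    if len(labels) == 0:
        raise ValueError("cannot label nodes without training data")
    winners = bmu_batch(model, train_features)
    overall = Counter(labels)

    node_labels: list[str | None] = [None] * model.n_nodes
    for node in range(model.n_nodes):
        votes = Counter(labels[winners == node])
        if not votes:
            continue
        best = max(votes.values())
        cands = [c for c, v in votes.items() if v == best]
        cands.sort(key=lambda c: (-overall[c], c))
        node_labels[node] = cands[0]

    filled = [i for i, lab in enumerate(node_labels) if lab is not None]
    if not filled:
        raise ValueError("no node won any training epoch")
    filled_cb = model.codebook[filled]
    for node in range(model.n_nodes):
        if node_labels[node] is None:
            diffs = filled_cb - model.codebook[node]
            nearest = filled[int(np.argmin(np.einsum("ij,ij->i", diffs, diffs)))]
            node_labels[node] = node_labels[nearest]

    model.node_labels = node_labels  # type: ignore[assignment]
    return model


def predict(model: SOMModel, features) -> np.ndarray:
    """Behaviour label of each epoch's BMU (pointwise, stateless)."""
    if model.node_labels is None:
        raise ValueError("model has no node labels; run label_nodes first")
    winners = bmu_batch(model, features)
    labels = np.asarray(model.node_labels, dtype=object)
    return labels[winners]
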