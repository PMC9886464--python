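"""Distance-weighted k-nearest-neighbour classification.

Each of the k nearest training points (Euclidean distance in per-feature
standardized space) votes for its class with weight 1/d; the predicted label
is the class with the largest summed weight.  A query coinciding exactly
with training points (d = 0) is decided by majority among the zero-distance
neighbours alone.  There is no iterative training: fitting stores the
standardized matrix and the standardizer statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from ._core import ValidationError

__all__ = ["WKNNModel", "fit", "predict", "predict_batch", "holdout_split",
           "save_model", "load_model", "cross_validate_k"]


@dataclass
class WKNNModel:
    """Fitted weighted-KNN model over standardized features."""

    train_matrix: np.ndarray       # (n, d) z-scored training features
    train_labels: np.ndarray       # (n,) class tags
    k: int
    feature_mean: np.ndarray       # (d,) training means
    feature_std: np.ndarray        # (d,) training deviations (0 -> 1)
    metric: str = "euclidean"
    classes: tuple[str, ...] = ()
    feature_names: tuple[str, ...] | None = None
    selected_indices: tuple[int, ...] | None = None
    sample_rate: float | None = None
    normalize: bool = True

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - self.feature_mean) / self.feature_std


def fit(features: np.ndarray, labels, k: int = 10, **metadata) -> WKNNModel:
    """Fit a weighted-KNN model: z-score per feature and store the data.

    A constant training column gets deviation 1 so standardization stays
    defined.  Extra keyword metadata (``feature_names``,
    ``selected_indices``, ``sample_rate``, ``normalize``) is carried on the
    model for pipeline bookkeeping.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if features.ndim != 2:
        raise ValidationError("features must be a 2-D matrix")
    n = features.shape[0]
    if labels.shape[0] != n:
        raise ValidationError("labels length must match the number of recordings")
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    classes = tuple(np.unique(labels).tolist())
    if len(classes) < 2:
        raise ValidationError("training data must contain at least 2 classes")
    mean = features.mean(axis=0)
    std = features.std(axis=0, ddof=1) if n > 1 else np.ones(features.shape[1])
    std = np.where(std == 0, 1.0, std)
    model = WKNNModel(
        train_matrix=(features - mean) / std,
        train_labels=labels.astype(str),
        k=k, feature_mean=mean, feature_std=std, classes=classes,
    )
    for key, value in metadata.items():
        setattr(model, key, value)
    return model


def _vote(model: WKNNModel, z: np.ndarray) -> tuple[str, dict[str, float]]:
    d = np.sqrt(((model.train_matrix - z) ** 2).sum(axis=1))
    nearest = np.argsort(d, kind="stable")[: model.k]
    d_near = d[nearest]
    labels_near = model.train_labels[nearest]

    if np.any(d_near == 0):
        zero_labels = labels_near[d_near == 0]
        # majority among exact matches; ties -> first encountered
        uniq, counts = np.unique(zero_labels, return_counts=True)
        best = uniq[np.argmax(counts)]
        winners = [lab for lab in zero_labels if
                   counts[list(uniq).index(lab)] == counts.max()]
        label = winners[0]
        shares = {c: 0.0 for c in model.classes}
        shares[label] = 1.0
        return str(label), shares

    weights = 1.0 / d_near
    shares = {c: 0.0 for c in model.classes}
    for lab, w in zip(labels_near, weights):
        shares[lab] += w
    total = sum(shares.values())
    shares = {c: w / total for c, w in shares.items()}
    best_weight = max(shares.values())
    # tie-break: class appearing first among the nearest neighbours
    for lab in labels_near:
        if np.isclose(shares[lab], best_weight):
            return str(lab), shares
    return str(max(shares, key=shares.get)), shares


def predict(model: WKNNModel, x: np.ndarray) -> tuple[str, dict[str, float]]:
    """Classify one feature vector; returns (label, per-class weight shares)."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != model.feature_mean.shape:
        raise ValidationError(
            f"query has {x.shape} features, model expects {model.feature_mean.shape}"
        )
    return _vote(model, model.standardize(x))


def predict_batch(model: WKNNModel, X: np.ndarray) -> np.ndarray:
    """Predicted labels for a (n, d) query matrix."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.feature_mean.size:
        raise ValidationError("query matrix has wrong feature dimension")
    return np.array([predict(model, row)[0] for row in X])


def holdout_split(features: np.ndarray, labels, train_fraction: float = 0.8,
                  seed: int = 0):
    """Stratified train/validation split, deterministic for a seed.

    Per-class proportions are preserved to within one recording.  Returns
    ``(X_train, y_train, X_val, y_val)``.
    """
    features = np.asarray(features)
    labels = np.asarray(labels)
    if not 0 < train_fraction < 1:
        raise ValidationError("train_fraction must be strictly between 0 and 1")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValidationError("every class needs at least 2 recordings to split")
    try:
        X_tr, X_va, y_tr, y_va = train_test_split(
            features, labels, train_size=train_fraction, stratify=labels,
            random_state=seed, shuffle=True,
        )
    except ValueError as exc:  # e.g. validation share smaller than n_classes
        raise ValidationError(f"cannot stratify split: {exc}") from exc
    return X_tr, y_tr, X_va, y_va


def cross_validate_k(features: np.ndarray, labels, k_grid=(1, 3, 5, 10, 15),
                     n_folds: int = 5, seed: int = 0) -> dict[int, float]:
    """Mean stratified cross-validated accuracy for each candidate k."""
    from sklearn.model_selection import StratifiedKFold

    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    results: dict[int, float] = {}
    for k in k_grid:
        accs = []
        for tr, va in skf.split(features, labels):
            model = fit(features[tr], labels[tr], k=min(k, tr.size))
            accs.append(float(np.mean(predict_batch(model, features[va]) == labels[va])))
        results[int(k)] = float(np.mean(accs))
    return results


def save_model(model: WKNNModel, path: str | Path) -> None:
    """Serialize the model to a single portable JSON file."""
    payload = {
        "schema": "pcgkit-wknn-1",
        "k": model.k,
        "metric": model.metric,
        "classes": list(model.classes),
        "feature_mean": model.feature_mean.tolist(),
        "feature_std": model.feature_std.tolist(),
        "train_matrix": model.train_matrix.tolist(),
        "train_labels": model.train_labels.tolist(),
        "feature_names": list(model.feature_names) if model.feature_names else None,
        "selected_indices": list(model.selected_indices)
        if model.selected_indices is not None else None,
        "sample_rate": model.sample_rate,
        "normalize": model.normalize,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> WKNNModel:
    """Load a model saved by :func:`save_model`."""
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != "pcgkit-wknn-1":
        raise ValidationError(f"unrecognized model schema in {path}")
    return WKNNModel(
        train_matrix=np.array(payload["train_matrix"], dtype=np.float64),
        train_labels=np.array(payload["train_labels"], dtype=str),
        k=int(payload["k"]),
        feature_mean=np.array(payload["feature_mean"], dtype=np.float64),
        feature_std=np.array(payload["feature_std"], dtype=np.float64),
        metric=payload["metric"],
        classes=tuple(payload["classes"]),
        feature_names=tuple(payload["feature_names"]) if payload["feature_names"] else None,
        selected_indices=tuple(payload["selected_indices"])
        if payload["selected_indices"] is not None else None,
        sample_rate=payload["sample_rate"],
        normalize=bool(payload["normalize"]),
    )
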