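"""End-to-end glue: features -> selection -> weighted KNN -> metrics.

The canonical training flow mirrors the diagnostic workflow: resample every
recording to the configured rate, optionally z-score it, extract the 26
features, split stratified 80/20, rank features by chi-square association on
the TRAINING split only, keep the top 15, fit the weighted KNN, and score
the held-out recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import evaluate as ev
from . import features as ft
from . import selection, wknn
from ._core import ValidationError
from .config import PipelineConfig
from .io import Signal, resample_to, zscore_normalize

__all__ = ["PipelineResult", "extract_matrix", "train_pipeline", "diagnose"]


@dataclass
class PipelineResult:
    """Everything the training/evaluation flow produces."""

    model: wknn.WKNNModel
    ranking: selection.FeatureRanking
    selected: np.ndarray
    confusion: ev.ConfusionMatrix
    per_class: dict[str, ev.ClassMetrics]
    macro: ev.ClassMetrics
    accuracy: float                  # overall multi-class accuracy, percent
    y_true: np.ndarray
    y_pred: np.ndarray


def _prepare(signal: Signal, config: PipelineConfig) -> Signal:
    sig = resample_to(signal, config.sample_rate)
    if config.normalize:
        sig = zscore_normalize(sig)
    return sig


def extract_matrix(signals, config: PipelineConfig | None = None):
    """Feature matrix (n, 26) and label array for a labeled signal collection."""
    config = config or PipelineConfig()
    rows, labels = [], []
    for sig in signals:
        prepared = _prepare(sig, config)
        fv = ft.mfcc_features(
            prepared, n_coeffs=config.mfcc_n_coeffs,
            frame_len=config.mfcc_frame_len, hop=config.mfcc_hop,
            n_filters=config.mfcc_n_filters,
            include_zeroth=config.mfcc_include_zeroth,
        )
        td = ft.time_domain_features(prepared)
        sq = ft.spectral_quality_features(prepared)
        values = np.concatenate([
            [td[name] for name in ft.TIME_DOMAIN_NAMES],
            [sq[name] for name in ft.SPECTRAL_NAMES],
            fv,
        ])
        rows.append(ft.FeatureVector(values).values)
        labels.append(sig.label)
    if any(lab is None for lab in labels):
        raise ValidationError("every signal must carry a class label")
    return np.vstack(rows), np.asarray(labels, dtype=str)


def train_pipeline(signals, config: PipelineConfig | None = None) -> PipelineResult:
    """Train and score the full pipeline on a labeled signal collection."""
    config = config or PipelineConfig()
    X, y = extract_matrix(signals, config)
    X_tr, y_tr, X_va, y_va = wknn.holdout_split(
        X, y, train_fraction=config.train_fraction, seed=config.seed)

    ranking = selection.chi2_rank(X_tr, y_tr, n_bins=config.n_bins,
                                  feature_names=ft.FEATURE_NAMES)
    selected = selection.select_top_k(ranking, k=config.top_k)

    model = wknn.fit(
        X_tr[:, selected], y_tr, k=config.knn_k,
        feature_names=tuple(ft.FEATURE_NAMES[i] for i in selected),
        selected_indices=tuple(int(i) for i in selected),
        sample_rate=config.sample_rate, normalize=config.normalize,
    )
    y_pred = wknn.predict_batch(model, X_va[:, selected])
    cm = ev.confusion(y_va, y_pred)
    per_class = {c: ev.class_metrics(cm, c) for c in cm.classes}
    macro = ev.macro_average(per_class)
    return PipelineResult(
        model=model, ranking=ranking, selected=selected, confusion=cm,
        per_class=per_class, macro=macro, accuracy=ev.overall_accuracy(cm),
        y_true=y_va, y_pred=y_pred,
    )


def diagnose(signal: Signal, model: wknn.WKNNModel,
             config: PipelineConfig | None = None):
    """Classify one recording with a trained model.

    The recording is resampled and normalized according to the model's
    stored metadata; the model's stored feature subset is applied
    automatically to the full 26-feature vector.
    """
    config = config or PipelineConfig()
    rate = model.sample_rate or config.sample_rate
    sig = resample_to(signal, rate)
    if model.normalize:
        sig = zscore_normalize(sig)
    fv = ft.extract_features(sig)
    if model.selected_indices is not None:
        x = fv.values[list(model.selected_indices)]
    else:
        x = fv.values
    if x.shape != model.feature_mean.shape:
        raise ValidationError(
            "feature dimension mismatch between recording and model: "
            f"got {x.shape[0]}, model expects {model.feature_mean.size}"
        )
    return wknn.predict(model, x)
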