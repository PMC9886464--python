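"""Chi-square feature ranking and top-k selection.

Each continuous feature is discretized into equal-frequency (quantile) bins;
a bins-by-classes contingency table is tested for independence with
Pearson's chi-square, and the feature's importance score is -ln(p).  The
quantile binning makes scores invariant under any strictly monotone
transform of a feature and under permutation of the recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from ._core import ValidationError

__all__ = ["FeatureRanking", "chi2_rank", "select_top_k"]


@dataclass
class FeatureRanking:
    """Per-feature p-values and importance scores with the ranked order.

    ``order`` sorts features by descending score, ties broken by original
    column index; ``selected`` is filled in by :func:`select_top_k`.
    """

    p_values: np.ndarray
    scores: np.ndarray
    order: np.ndarray
    feature_names: tuple[str, ...] | None = None
    selected: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        """Ranking as a DataFrame (feature, p_value, score, selected flag)."""
        n = self.scores.size
        names = self.feature_names or tuple(f"f{i}" for i in range(n))
        sel = set() if self.selected is None else set(self.selected.tolist())
        return pd.DataFrame({
            "feature": names,
            "p_value": self.p_values,
            "score": self.scores,
            "selected": [i in sel for i in range(n)],
        })


def _quantile_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin codes; duplicate quantile edges are merged."""
    codes = pd.qcut(x, q=n_bins, labels=False, duplicates="drop")
    return np.asarray(codes)


def chi2_rank(features: np.ndarray, labels, n_bins: int = 10,
              feature_names: tuple[str, ...] | None = None) -> FeatureRanking:
    """Rank features by chi-square association with the class label.

    Parameters
    ----------
    features
        (n_recordings, n_features) matrix.
    labels
        Class tag per recording; at least two classes must be present.
    n_bins
        Number of quantile bins per feature.  A constant feature (single
        bin) has no association and gets p = 1, score = 0.

    Returns
    -------
    FeatureRanking
        p-values, scores = -ln(p) (p floored at the smallest positive
        double so scores stay finite), and the descending-score order.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if features.ndim != 2:
        raise ValidationError("features must be a 2-D matrix")
    if labels.shape[0] != features.shape[0]:
        raise ValidationError("labels length must match the number of recordings")
    if np.unique(labels).size < 2:
        raise ValidationError("chi-square ranking needs at least 2 classes")

    n_features = features.shape[1]
    p_values = np.ones(n_features)
    for j in range(n_features):
        codes = _quantile_bins(features[:, j], n_bins)
        if np.unique(codes).size < 2:
            continue  # constant feature: p stays 1
        table = pd.crosstab(codes, labels).to_numpy()
        _, p, _, _ = chi2_contingency(table, correction=False)
        p_values[j] = min(max(p, np.finfo(float).tiny), 1.0)

    scores = -np.log(p_values)
    order = np.lexsort((np.arange(n_features), -scores))
    return FeatureRanking(p_values=p_values, scores=scores, order=order,
                          feature_names=feature_names)


def select_top_k(ranking: FeatureRanking, k: int = 15) -> np.ndarray:
    """Indices of the ``k`` highest-scoring features.

    Ties are broken by original feature order (already encoded in
    ``ranking.order``), so selection is deterministic.
    """
    n = ranking.scores.size
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    selected = ranking.order[:k].copy()
    ranking.selected = selected
    return selected
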