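"""Mutual-information feature ranking and selection.

Each feature is scored by its mutual information with the binary class label,

    I(X; Y) = sum_{x,y} p(x, y) * ln[ p(x, y) / (p(x) p(y)) ],

estimated from the empirical joint distribution after discretising the
feature into at most ``n_bins`` equal-frequency bins (features with few
distinct values keep their values as categories).  Natural logarithms are
used, so scores are in nats; only the ranking matters for selection.
Features are ranked by descending score with ties broken by ascending column
index, and the top ``k`` (default 700) are retained.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .encoders import FeatureMatrix

logger = logging.getLogger(__name__)

DEFAULT_K = 700
DEFAULT_BINS = 20


@dataclass
class SelectionResult:
    """Scores, ranking, retained subset and its per-category composition."""

    scores: np.ndarray
    ranking: np.ndarray
    selected: np.ndarray
    selected_names: list[str]
    k: int
    category_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "k": self.k,
            "scores": self.scores.tolist(),
            "ranking": self.ranking.tolist(),
            "selected": self.selected.tolist(),
            "selected_names": self.selected_names,
            "category_counts": self.category_counts,
            "category_percent": category_report(self),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning into at most n_bins codes."""
    uniq = np.unique(x)
    if uniq.size <= n_bins:
        return np.searchsorted(uniq, x)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right")


def mi_score(feature_values, labels, n_bins: int = DEFAULT_BINS) -> float:
    """Empirical mutual information (nats) between a feature and binary labels."""
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(labels)
    if x.shape != y.shape:
        raise ValueError("feature and labels must have equal length")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels contain a single class")
    codes = _discretize(x, n_bins)
    n = len(x)
    joint = np.zeros((codes.max() + 1, classes.size))
    ycodes = np.searchsorted(classes, y)
    np.add.at(joint, (codes, ycodes), 1.0)
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    ratio = np.ones_like(pxy)
    ratio[mask] = pxy[mask] / (px @ py)[mask]
    return float(np.sum(pxy[mask] * np.log(ratio[mask])))


def rank_and_select(
    matrix: FeatureMatrix, k: int = DEFAULT_K, n_bins: int = DEFAULT_BINS
) -> SelectionResult:
    """Score all columns, rank descending (index ascending on ties), keep top-k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n_cols = matrix.n_features
    values = matrix.X.to_numpy()
    scores = np.array([mi_score(values[:, j], matrix.y, n_bins) for j in range(n_cols)])
    ranking = np.lexsort((np.arange(n_cols), -scores))
    if k > n_cols:
        warnings.warn(
            f"k={k} exceeds {n_cols} columns; selecting all", UserWarning, stacklevel=2
        )
    selected = ranking[: min(k, n_cols)]
    names = [matrix.X.columns[j] for j in selected]
    cats = Counter(name.split("_", 1)[0] for name in names)
    return SelectionResult(scores, ranking, selected, names, k, dict(cats))


def category_report(result: SelectionResult) -> dict[str, float]:
    """Percentage of the retained set per category, rounded to 2 decimals."""
    total = len(result.selected)
    if total == 0:
        return {}
    return {
        cat: round(100.0 * cnt / total, 2)
        for cat, cnt in sorted(result.category_counts.items())
    }
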