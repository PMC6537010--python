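"""Leave-one-sample-out KNN evaluation and class-membership profiles.

Evaluation follows the protocol standard in the block-histogram descriptor
literature: every sample in turn is held out and classified against all
remaining samples with a KNN vote (``k = 1`` by default, which also removes
vote-tie ambiguity). Features are histograms, so both Euclidean and the
epsilon-guarded chi-square histogram distance are supported.

:func:`expression_components` computes the inverse-square-distance class
membership weights ``Ra_i = (1/d_i**2) / sum_j (1/d_j**2)`` of a sample
against per-class centre features; the profile sums to one and concentrates
on the nearest class.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "LabeledFeatures",
    "EvalResult",
    "pairwise_distances",
    "loso_knn_evaluate",
    "class_centers",
    "expression_components",
]

METRICS = ("euclidean", "chi2")

_CHI2_EPS = 1e-10


@dataclass
class LabeledFeatures:
    """A feature matrix with per-row class labels and sample ids."""

    features: np.ndarray
    labels: np.ndarray
    ids: list | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D (samples x dims) matrix")
        if len(self.labels) != self.features.shape[0]:
            raise ValueError("labels length must match the number of feature rows")
        if self.ids is None:
            self.ids = [f"sample_{i:04d}" for i in range(len(self.labels))]
        elif len(self.ids) != len(self.labels):
            raise ValueError("ids length must match the number of samples")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass
class EvalResult:
    """Outcome of a leave-one-sample-out run."""

    accuracy: float
    confusion: pd.DataFrame  # rows = true class, columns = predicted class
    predictions: pd.DataFrame  # per-fold id, true, predicted, correct

    def summary(self) -> str:
        lines = [
            f"samples:  {len(self.predictions)}",
            f"accuracy: {self.accuracy:.4f}",
            "",
            "confusion matrix (rows true, columns predicted):",
            self.confusion.to_string(),
        ]
        return "\n".join(lines)


def _chi2_distances(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Chi-square histogram distance ``0.5 * sum (a-b)^2 / (a+b+eps)``."""
    out = np.empty((x.shape[0], y.shape[0]))
    for i, row in enumerate(x):
        num = (row[None, :] - y) ** 2
        den = row[None, :] + y + _CHI2_EPS
        out[i] = 0.5 * (num / den).sum(axis=1)
    return out


def pairwise_distances(x: np.ndarray, y: np.ndarray | None = None, metric: str = "euclidean") -> np.ndarray:
    """Distance matrix between rows of ``x`` and rows of ``y`` (or ``x``)."""
    x = np.asarray(x, dtype=np.float64)
    y = x if y is None else np.asarray(y, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    if y.ndim == 1:
        y = y[None, :]
    if metric == "euclidean":
        return cdist(x, y, metric="euclidean")
    if metric == "chi2":
        return _chi2_distances(x, y)
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def loso_knn_evaluate(data: LabeledFeatures, k: int = 1, metric: str = "euclidean") -> EvalResult:
    """Leave-one-sample-out KNN over a labeled feature matrix.

    Each sample is predicted by the majority label of its ``k`` nearest
    other samples under ``metric``; a vote tie falls back to the single
    nearest neighbour's label. Fully deterministic: neighbour order is the
    stable sort of distances, so equal distances resolve by sample index.
    """
    n = data.n_samples
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} requires at least k+1={k + 1} samples, got {n}")
    if len(data.classes) < 2:
        raise ValueError("evaluation requires at least 2 classes")

    dist = pairwise_distances(data.features, metric=metric)
    np.fill_diagonal(dist, np.inf)

    preds = []
    for i in range(n):
        order = np.argsort(dist[i], kind="stable")
        neighbours = order[:k]
        votes = Counter(data.labels[j] for j in neighbours)
        top = max(votes.values())
        winners = {label for label, c in votes.items() if c == top}
        if len(winners) == 1:
            pred = winners.pop()
        else:  # tie: nearest neighbour whose label is among the tied winners
            pred = next(data.labels[j] for j in neighbours if data.labels[j] in winners)
        preds.append(pred)

    preds = np.asarray(preds)
    correct = preds == data.labels
    classes = list(data.classes)
    confusion = (
        pd.crosstab(pd.Series(data.labels, name="true"), pd.Series(preds, name="predicted"))
        .reindex(index=classes, columns=classes, fill_value=0)
    )
    predictions = pd.DataFrame(
        {"id": data.ids, "true": data.labels, "predicted": preds, "correct": correct}
    )
    return EvalResult(
        accuracy=float(correct.mean()), confusion=confusion, predictions=predictions
    )


def class_centers(data: LabeledFeatures, method: str = "mean") -> dict:
    """Per-class centre features.

    ``method="mean"`` (default) is the arithmetic mean feature of the class;
    ``method="medoid"`` picks the class sample minimising the summed
    Euclidean distance to its classmates.
    """
    centers = {}
    for label in data.classes:
        rows = data.features[data.labels == label]
        if rows.shape[0] == 0:
            raise ValueError(f"class {label!r} is empty")
        if method == "mean":
            centers[label] = rows.mean(axis=0)
        elif method == "medoid":
            d = pairwise_distances(rows)
            centers[label] = rows[int(np.argmin(d.sum(axis=1)))]
        else:
            raise ValueError("method must be 'mean' or 'medoid'")
    return centers


def expression_components(sample, centers: dict, metric: str = "euclidean") -> pd.Series:
    """Inverse-square-distance class membership weights of one sample.

    ``Ra_i = (1/d_i**2) / sum_j (1/d_j**2)`` with ``d_i`` the distance from
    the sample to class ``i``'s centre. The formula is undefined at
    ``d_i = 0``; in that limit the full mass is assigned to the
    zero-distance class(es), split equally.
    """
    sample = np.asarray(sample, dtype=np.float64)
    labels = list(centers)
    matrix = np.stack([np.asarray(centers[label], dtype=np.float64) for label in labels])
    if matrix.shape[1] != sample.shape[-1]:
        raise ValueError(
            f"sample has {sample.shape[-1]} dims but centers have {matrix.shape[1]}"
        )
    d = pairwise_distances(sample[None, :], matrix, metric=metric)[0]
    zero = d == 0
    if zero.any():
        weights = zero.astype(np.float64)
    else:
        weights = 1.0 / d**2
    return pd.Series(weights / weights.sum(), index=labels, name="Ra")
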