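"""SURF (Spatial Uniform ReliefF) feature ranking and top-k selection.

ReliefF scores a feature by how well it separates each instance from
nearby instances of the other class (misses) relative to nearby instances
of the same class (hits). SURF replaces ReliefF's tuned k-nearest-neighbor
rule with a single distance threshold T — the mean Euclidean distance over
all unordered instance pairs — so every instance closer than T is a
neighbor and no k needs choosing. All instances are used (no sampling),
which makes the weights deterministic and invariant to sample order.

Features are min-max scaled to [0, 1] over the sample set before distance
and difference computations, the standard Relief convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import DataError

__all__ = ["SampleSet", "FeatureRanking", "surf_rank", "select_top"]


@dataclass
class SampleSet:
    """A labeled feature matrix: X (n_samples x n_features), binary y."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    point_ids: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise DataError("X must be 2D")
        if self.y.shape != (self.X.shape[0],):
            raise DataError("y must have one label per sample")
        if not np.all(np.isin(self.y, (0, 1))):
            raise DataError("labels must be binary 0/1")
        if not np.all(np.isfinite(self.X)):
            raise DataError("X contains non-finite values")
        if len(self.feature_names) != self.X.shape[1]:
            raise DataError("feature_names length must equal n_features")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class FeatureRanking:
    """Per-feature SURF weights plus the descending-weight ordering."""

    weights: np.ndarray
    order: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        if sorted(self.order.tolist()) != list(range(self.weights.size)):
            raise DataError("order must be a permutation of feature indices")


def _minmax_scale(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0] = 1.0  # constant features map to 0 everywhere
    return (X - lo) / span


def surf_rank(data: SampleSet) -> FeatureRanking:
    """Rank features by SURF relevance weight.

    For each instance i, neighbors are all j with d(i, j) below the mean
    pairwise distance T. A feature's weight accumulates
    ``+diff(f, i, j) / (n * m_i)`` over miss neighbors (different class)
    and ``-diff(f, i, j) / (n * h_i)`` over hit neighbors, where diff is
    the absolute scaled value difference, n the sample count and m_i / h_i
    instance i's miss/hit neighbor counts. Deterministic; ties in the
    ranking break toward the smaller feature index.
    """
    classes, counts = np.unique(data.y, return_counts=True)
    if classes.size < 2:
        raise DataError(
            "ReliefF-family weights undefined without both classes present"
        )
    if counts.min() < 2:
        raise DataError("need at least 2 samples per class")

    X = _minmax_scale(data.X)
    y = data.y
    n = X.shape[0]
    dists = squareform(pdist(X))
    threshold = pdist(X).mean()

    weights = np.zeros(X.shape[1])
    for i in range(n):
        neigh = (dists[i] < threshold) & (np.arange(n) != i)
        if not neigh.any():
            continue
        same = neigh & (y == y[i])
        diff_cls = neigh & (y != y[i])
        h_i, m_i = int(same.sum()), int(diff_cls.sum())
        if m_i:
            weights += np.abs(X[diff_cls] - X[i]).sum(axis=0) / (n * m_i)
        if h_i:
            weights -= np.abs(X[same] - X[i]).sum(axis=0) / (n * h_i)

    # stable argsort on (-weight, index): ties break toward ascending index
    order = np.lexsort((np.arange(weights.size), -weights))
    return FeatureRanking(
        weights=weights, order=order, feature_names=list(data.feature_names)
    )


def select_top(ranking: FeatureRanking, k: int) -> np.ndarray:
    """The indices of the k highest-weighted features, best first."""
    n = ranking.weights.size
    if not 1 <= k <= n:
        raise DataError(f"k must be in [1, {n}], got {k}")
    return ranking.order[:k].copy()


def ranking_to_rows(ranking: FeatureRanking) -> list[tuple[int, str, float]]:
    """(rank, feature_name, weight) rows for CSV export."""
    return [
        (r + 1, ranking.feature_names[i], float(ranking.weights[i]))
        for r, i in enumerate(ranking.order)
    ]
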