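"""Pixel-level confusion counts and overlap metrics for en-face maps.

The four reported metrics are

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    dice        = 2 TP / (2 TP + FP + FN)
    jaccard     = TP / (TP + FP + FN)

computed over en-face map pixels. On a volume without any true ERM
(TP + FN = 0) sensitivity, Dice and Jaccard are undefined and reported as
``None``; only specificity is meaningful there. For a single confusion
matrix Dice and Jaccard obey J = D / (2 - D).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DataError, ERMMap

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "compute_metrics",
    "aggregate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DataError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    """Metric values in [0, 1]; ``None`` marks an undefined metric."""

    sensitivity: float | None
    specificity: float | None
    dice: float | None
    jaccard: float | None
    volume_id: str = ""
    stage: str = "classification"


def confusion(pred: ERMMap, truth: ERMMap) -> ConfusionCounts:
    """Pixel-wise confusion tallies between a predicted and a truth map."""
    if pred.grid.shape != truth.grid.shape:
        raise DataError(
            f"map shapes differ: {pred.grid.shape} vs {truth.grid.shape}"
        )
    p = pred.grid.astype(bool)
    t = truth.grid.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def compute_metrics(
    c: ConfusionCounts, volume_id: str = "", stage: str = "classification"
) -> MetricReport:
    """Sensitivity, specificity, Dice and Jaccard from confusion counts."""
    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return MetricReport(
        sensitivity=ratio(c.tp, c.tp + c.fn),
        specificity=ratio(c.tn, c.tn + c.fp),
        dice=ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        jaccard=ratio(c.tp, c.tp + c.fp + c.fn),
        volume_id=volume_id,
        stage=stage,
    )


def slice_level_confusion(pred: ERMMap, truth: ERMMap) -> ConfusionCounts:
    """Optional slice-level tallies: a slice is positive if any column is."""
    if pred.grid.shape != truth.grid.shape:
        raise DataError("map shapes differ")
    p = pred.grid.any(axis=1)
    t = truth.grid.any(axis=1)
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def aggregate(reports: list[MetricReport]) -> dict[str, dict[str, float]]:
    """Mean and sample (n-1) standard deviation per metric across volumes.

    Undefined metrics are excluded; a metric undefined in every report is
    omitted from the output. Single-volume aggregates report std 0 with
    ``n`` = 1.
    """
    if not reports:
        raise DataError("no reports to aggregate")
    out: dict[str, dict[str, float]] = {}
    for metric in ("sensitivity", "specificity", "dice", "jaccard"):
        vals = [
            getattr(r, metric)
            for r in reports
            if getattr(r, metric) is not None
        ]
        if not vals:
            continue
        arr = np.asarray(vals, dtype=float)
        out[metric] = {
            "mean": float(arr.mean()),
            "std": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "n": int(arr.size),
        }
    return out
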