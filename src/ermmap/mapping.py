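"""En-face ERM map assembly and morphological refinement.

Per-slice prediction vectors are stacked row-wise into a 2D en-face map
(row i = slice i). Because the classifier labels each ILM point
independently while a real membrane is a contiguous sheet, the raw map is
refined in two steps: small connected components (spurious detections) are
removed, then a morphological closing unifies nearby positive regions.
The two parameters — the component area threshold and the closing disk
radius — are chosen by exhaustive grid search maximizing mean Dice overlap
with ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from skimage.morphology import closing, disk, remove_small_objects

from .core import DataError, ERMMap
from .metrics import compute_metrics, confusion

__all__ = [
    "PostprocessParams",
    "DEFAULT_PARAM_GRID",
    "build_map",
    "refine_map",
    "optimize_postprocess",
]


@dataclass(frozen=True)
class PostprocessParams:
    """min_area: smallest surviving component (px); closing_radius: disk px."""

    min_area: int = 25
    closing_radius: int = 2
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.min_area < 0 or self.closing_radius < 0:
            raise DataError("min_area and closing_radius must be >= 0")
        if self.connectivity not in (4, 8):
            raise DataError("connectivity must be 4 or 8")


DEFAULT_PARAM_GRID = tuple(
    PostprocessParams(a, r)
    for a, r in product((0, 10, 25, 50, 100, 200), (0, 1, 2, 3, 5, 7))
)


def build_map(vectors, provenance: str = "raw") -> ERMMap:
    """Stack per-slice label vectors (slice order) into an en-face map."""
    vecs = [np.asarray(v) for v in vectors]
    if not vecs:
        raise DataError("no prediction vectors supplied")
    widths = {v.shape for v in vecs}
    if len(widths) != 1 or vecs[0].ndim != 1:
        raise DataError(f"ragged prediction vectors: shapes {sorted(widths)}")
    return ERMMap(np.vstack(vecs), provenance=provenance)


def refine_map(erm_map: ERMMap, params: PostprocessParams) -> ERMMap:
    """Area-filter then close the binary map.

    Step 1 removes every connected component smaller than ``min_area``
    pixels (8- or 4-connectivity); step 2 applies binary closing with a
    disk of ``closing_radius`` (the map is zero-padded by the radius first,
    so closing is extensive everywhere and the operation is idempotent).
    """
    mask = erm_map.grid.astype(bool)
    if params.min_area > 0:
        # drop components with area <= min_area - 1, i.e. area < min_area
        mask = remove_small_objects(
            mask,
            max_size=params.min_area - 1,
            connectivity=2 if params.connectivity == 8 else 1,
        )
    r = params.closing_radius
    if r > 0:
        padded = np.pad(mask, r)
        padded = closing(padded, disk(r))
        mask = padded[r:-r, r:-r]
    return ERMMap(mask.astype(np.uint8), provenance="refined")


def optimize_postprocess(
    raw_maps: list[ERMMap],
    truth_maps: list[ERMMap],
    grid=DEFAULT_PARAM_GRID,
) -> tuple[PostprocessParams, float]:
    """Exhaustive grid search maximizing mean Dice over the volumes.

    Volumes with all-negative ground truth have undefined Dice and are
    skipped; if every volume is ERM-free the search is impossible and an
    error points the caller to specificity-based selection instead. Ties
    break toward the smaller ``min_area``, then the smaller radius.
    Returns the winning parameters and their mean Dice.
    """
    if len(raw_maps) != len(truth_maps) or not raw_maps:
        raise DataError("need matching, non-empty raw and truth map lists")
    scored = [
        (m, t) for m, t in zip(raw_maps, truth_maps) if t.grid.any()
    ]
    if not scored:
        raise DataError(
            "Dice is undefined on all-negative ground truth: all supplied "
            "volumes are ERM-free; select parameters by specificity instead"
        )
    grid = sorted(grid, key=lambda p: (p.min_area, p.closing_radius))
    best: tuple[PostprocessParams, float] | None = None
    for params in grid:
        dices = []
        for raw, truth in scored:
            refined = refine_map(raw, params)
            report = compute_metrics(confusion(refined, truth))
            dices.append(report.dice if report.dice is not None else 0.0)
        mean_dice = float(np.mean(dices))
        if best is None or mean_dice > best[1]:
            best = (params, mean_dice)
    return best
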