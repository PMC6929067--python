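"""Core containers and error types shared across the pipeline.

Conventions: a B-scan is stored row-major with row 0 at the top of the scan
(vitreous side); pixel intensities are handled internally as floats in
``[0, 1]`` (8-bit images are divided by 255 on load). The en-face map has one
row per B-scan, in acquisition order, and one column per lateral A-scan
position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ErmmapError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(ErmmapError):
    """Invalid parameter or geometry configuration."""


class DataError(ErmmapError):
    """Malformed, inconsistent or missing input data."""


class StageError(ErmmapError):
    """A pipeline stage failed during execution."""


@dataclass
class BScan:
    """One grayscale cross-sectional retinal scan.

    ``pixels`` is a 2D float array in [0, 1]; row 0 is the vitreous side.
    """

    pixels: np.ndarray
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise DataError("BScan pixels must be a non-empty 2D array")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class OCTVolume:
    """An ordered stack of equidistant B-scans (a C-scan).

    ``data`` has shape (n_slices, height, width), float in [0, 1]; slice
    order matches acquisition order and hence the row order of the en-face
    map.
    """

    data: np.ndarray
    volume_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.size == 0:
            raise DataError("OCTVolume data must be a non-empty 3D array")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    def __len__(self) -> int:
        return self.n_slices

    def scan(self, i: int) -> BScan:
        return BScan(self.data[i], slice_index=i)

    def scans(self) -> list[BScan]:
        return [self.scan(i) for i in range(self.n_slices)]


@dataclass
class ILMContour:
    """Per-column row coordinate of the inner limiting membrane surface.

    One (floating point) row value per image column; the contour spans the
    full scan width.
    """

    rows: np.ndarray
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 1 or self.rows.size == 0:
            raise DataError("ILMContour rows must be a non-empty 1D array")
        if not np.all(np.isfinite(self.rows)):
            raise DataError("ILMContour rows must be finite everywhere")

    @property
    def width(self) -> int:
        return self.rows.size


@dataclass
class ERMMap:
    """Binary en-face map: row i holds the per-column ERM labels of slice i."""

    grid: np.ndarray
    provenance: str = "raw"

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2 or grid.size == 0:
            raise DataError("ERMMap grid must be a non-empty 2D array")
        vals = np.unique(grid)
        if not np.all(np.isin(vals, (0, 1))):
            raise DataError(
                f"ERMMap grid must be binary (0/1); found values {vals[:5]}"
            )
        self.grid = grid.astype(np.uint8)

    @property
    def n_slices(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]


@dataclass
class AnnotatedVolume:
    """A volume bundled with its ILM contours and (optionally) ground truth."""

    volume: OCTVolume
    contours: list[ILMContour]
    truth: ERMMap | None = None
    true_ilm: np.ndarray | None = None  # (n_slices, width) float, if known

    def __post_init__(self) -> None:
        if len(self.contours) != self.volume.n_slices:
            raise DataError("one contour per slice required")
        if self.truth is not None and (
            self.truth.n_slices != self.volume.n_slices
            or self.truth.width != self.volume.width
        ):
            raise DataError("truth map shape must match the volume")
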