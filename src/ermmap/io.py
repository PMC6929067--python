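"""Reading and writing OCT image stacks and en-face label maps.

Volumes are plain directories of grayscale PNG/TIFF images, one per B-scan,
ordered by the numeric suffix of their filenames. Readers reject
silently-corrupting inputs (mixed dimensions, colour images) rather than
coercing them.
"""

from __future__ import annotations

import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .core import DataError, ERMMap, OCTVolume

__all__ = ["load_volume", "save_map", "load_map"]

_IMAGE_EXTS = {".png", ".tif", ".tiff"}


def _numeric_key(path: Path) -> tuple:
    """Sort key: trailing number in the stem, then the name for stability."""
    m = re.search(r"(\d+)(?!.*\d)", path.stem)
    return (int(m.group(1)) if m else -1, path.name)


def _read_gray(path: Path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3:
        if img.shape[2] == 1:
            img = img[:, :, 0]
        elif np.all(img[:, :, :3] == img[:, :, :1]):
            img = img[:, :, 0]  # gray stored as identical channels
        else:
            raise DataError(f"{path.name}: colour image, expected grayscale")
    if img.ndim != 2:
        raise DataError(f"{path.name}: unsupported image shape {img.shape}")
    if img.dtype == np.uint16:
        return img.astype(float) / 65535.0
    return img.astype(float) / 255.0


def load_volume(dir_path, volume_id: str | None = None) -> OCTVolume:
    """Load a directory of grayscale B-scan images as one volume.

    Slices are ordered by the numeric suffix of their filenames
    (``slice_2`` loads before ``slice_10``); intensities are scaled to
    [0, 1]. Ground-truth files written by the phantom generator
    (``true_map.png``) are ignored.
    """
    d = Path(dir_path)
    if not d.is_dir():
        raise DataError(f"volume directory not found: {d}")
    paths = sorted(
        (
            p
            for p in d.iterdir()
            if p.suffix.lower() in _IMAGE_EXTS and p.name != "true_map.png"
        ),
        key=_numeric_key,
    )
    if not paths:
        raise DataError(f"no grayscale images found in {d}")
    slices = []
    shape = None
    for p in paths:
        img = _read_gray(p)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise DataError(
                f"{p.name}: dimensions {img.shape} differ from first slice {shape}"
            )
        slices.append(img)
    return OCTVolume(np.stack(slices), volume_id=volume_id or d.name)


def save_map(erm_map: ERMMap, path) -> None:
    """Save a binary en-face map losslessly as PNG with a CSV twin.

    The PNG stores ERM pixels as 255 (white); the CSV lists one
    ``slice,column`` row per positive pixel.
    """
    path = Path(path)
    if path.suffix.lower() != ".png":
        raise DataError("map path must end in .png")
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, erm_map.grid * np.uint8(255))
    with open(path.with_suffix(".csv"), "w") as fh:
        fh.write("slice,column\n")
        for s, c in zip(*np.nonzero(erm_map.grid)):
            fh.write(f"{s},{c}\n")


def load_map(path, provenance: str = "raw") -> ERMMap:
    """Load a binary PNG map saved by :func:`save_map`."""
    img = iio.imread(Path(path))
    if img.ndim != 2:
        raise DataError(f"{path}: map must be a single-channel image")
    vals = np.unique(img)
    if not np.all(np.isin(vals, (0, 255))):
        raise DataError(f"{path}: map must be binary 0/255, found {vals[:5]}")
    return ERMMap((img > 0).astype(np.uint8), provenance=provenance)
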