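"""The 452-value descriptor of an ILM point's neighbourhood.

Each ILM point is characterized through a vertical rectangular window of
five stacked square sub-windows, centered laterally on the point and
vertically on the ILM row: sub-windows 1-2 sample the vitreous/ERM space
above the surface, 3 straddles it, 4-5 sample the retinal tissue below.
From this window a fixed-order vector of 452 features is computed:

    ==================  =====  ==========================================
    category            count  contents
    ==================  =====  ==========================================
    pca                    10  projection on the 10 leading principal
                               components of the training windows
    glcm                   16  contrast/correlation/energy/homogeneity at
                               4 offsets (0/45/90/135 deg, distance 1) on
                               a 16-level quantized window
    gabor                 160  4 wavelengths x 8 orientations, mean
                               response magnitude in each sub-window
    lbp                    64  full histogram of P=6, R=1 binary codes
    laws                   28  mean + std of 14 symmetric-pair 5x5 Laws
                               texture-energy maps
    window                 75  15 intensity statistics per sub-window
    intensity_global       13  13 intensity statistics of the rectangle
    glih                    5  5-bin gray-level histogram of the rectangle
    hog                    81  3x3 cells x 9 orientation bins, one
                               L2-normalized block
    ==================  =====  ==========================================

Intensities are assumed in [0, 1]; histogram bins are fixed over that
range so the features respond to absolute reflectivity (the ERM is
hyper-reflective by definition, so intensity sensitivity is intentional).
Gabor, Laws and LBP responses are computed once per B-scan and pooled per
window, which is equivalent to filtering the window with full image
context and considerably faster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from skimage.feature import graycomatrix, graycoprops, hog, local_binary_pattern
from sklearn.decomposition import PCA

from .core import BScan, ConfigurationError, DataError, ErmmapError, ILMContour

__all__ = [
    "WindowGeometry",
    "WindowOutOfBounds",
    "PCABasis",
    "FeatureRegistry",
    "REGISTRY",
    "fit_pca_basis",
    "extract_window",
    "eligible_columns",
    "extract_features",
    "ScanFeatureExtractor",
]

N_SUB = 5
GABOR_WAVELENGTHS = (2.0, 4.0, 8.0, 16.0)  # px per cycle
N_ORIENTATIONS = 8
GLCM_PROPS = ("contrast", "correlation", "energy", "homogeneity")
GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
GLCM_LEVELS = 16
LBP_P, LBP_R = 6, 1
STAT_NAMES = (
    "mean", "std", "min", "max", "median", "range",
    "skewness", "kurtosis", "entropy", "energy",
)
_ENTROPY_BINS = 32

_LAWS_1D = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "W5": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
}
# 14 rotation-tolerant energy maps: 10 averaged cross pairs + 4 diagonals
_LAWS_PAIRS = [
    ("L5", "E5"), ("L5", "S5"), ("L5", "W5"), ("L5", "R5"),
    ("E5", "S5"), ("E5", "W5"), ("E5", "R5"),
    ("S5", "W5"), ("S5", "R5"), ("W5", "R5"),
]
_LAWS_DIAG = ["E5", "S5", "W5", "R5"]


class WindowOutOfBounds(ErmmapError):
    """The requested window does not fit inside the scan (skip the point)."""


@dataclass
class WindowGeometry:
    """Geometry of the rectangular analysis window.

    ``sub_side`` is the (odd) side of each square sub-window; the full
    rectangle is ``sub_side`` wide and ``5 * sub_side`` tall, centered
    laterally on the ILM point and vertically on the (rounded) ILM row.
    """

    sub_side: int = 15
    n_sub: int = N_SUB

    def __post_init__(self) -> None:
        if self.n_sub != N_SUB:
            raise ConfigurationError(f"n_sub is fixed at {N_SUB}")
        if self.sub_side < 5 or self.sub_side % 2 == 0:
            raise ConfigurationError("sub_side must be odd and >= 5")

    @property
    def win_height(self) -> int:
        return self.n_sub * self.sub_side

    def bounds(self, ilm_row: float, column: int) -> tuple[int, int]:
        """(top, left) of the window; may lie outside the image."""
        top = int(round(ilm_row)) - self.win_height // 2
        left = column - self.sub_side // 2
        return top, left

    def fits(self, ilm_row: float, column: int, shape: tuple[int, int]) -> bool:
        top, left = self.bounds(ilm_row, column)
        return (
            top >= 0
            and left >= 0
            and top + self.win_height <= shape[0]
            and left + self.sub_side <= shape[1]
        )


@dataclass
class PCABasis:
    """Mean and leading orthonormal components of vectorized training windows."""

    mean: np.ndarray
    components: np.ndarray  # (n_components, window_pixels)
    window_shape: tuple[int, int]

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def project(self, window: np.ndarray) -> np.ndarray:
        vec = np.asarray(window, dtype=float).ravel()
        if vec.size != self.mean.size:
            raise DataError(
                f"window has {vec.size} pixels, basis expects {self.mean.size}"
            )
        return (vec - self.mean) @ self.components.T


def fit_pca_basis(windows, n_components: int = 10) -> PCABasis:
    """Fit the PCA feature basis on a set of identically shaped windows."""
    arr = np.asarray([np.asarray(w, dtype=float) for w in windows])
    if arr.ndim != 3:
        raise DataError("windows must all share one 2D shape")
    if arr.shape[0] < n_components:
        raise DataError(
            f"need at least {n_components} training windows, got {arr.shape[0]}"
        )
    flat = arr.reshape(arr.shape[0], -1)
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(flat)
    return PCABasis(
        mean=pca.mean_,
        components=pca.components_,
        window_shape=(arr.shape[1], arr.shape[2]),
    )


class FeatureRegistry:
    """Canonical ordering and naming of the 452 features."""

    def __init__(self, geom: WindowGeometry | None = None) -> None:
        geom = geom or WindowGeometry()
        names: list[str] = []
        names += [f"pca_{i:02d}" for i in range(10)]
        names += [
            f"glcm_{p}_{d}deg"
            for p in GLCM_PROPS
            for d in (0, 45, 90, 135)
        ]
        names += [
            f"gabor_w{int(w)}_o{o}_sub{s + 1}"
            for w in GABOR_WAVELENGTHS
            for o in range(N_ORIENTATIONS)
            for s in range(N_SUB)
        ]
        names += [f"lbp_{i:02d}" for i in range(2**LBP_P)]
        laws_maps = [f"{a}{b}" for a, b in _LAWS_PAIRS] + [
            f"{k}{k}" for k in _LAWS_DIAG
        ]
        names += [f"laws_{m}_{s}" for m in laws_maps for s in ("mean", "std")]
        names += [
            f"win{s + 1}_{stat}"
            for s in range(N_SUB)
            for stat in STAT_NAMES + tuple(f"hist{b + 1}" for b in range(5))
        ]
        names += [
            f"global_{stat}"
            for stat in STAT_NAMES + ("p25", "p75", "variance")
        ]
        names += [f"glih_{b + 1}" for b in range(5)]
        names += [
            f"hog_cell{r}{c}_bin{b}"
            for r in range(3)
            for c in range(3)
            for b in range(9)
        ]
        self.names = names
        self.category_slices = {
            "pca": slice(0, 10),
            "glcm": slice(10, 26),
            "gabor": slice(26, 186),
            "lbp": slice(186, 250),
            "laws": slice(250, 278),
            "window": slice(278, 353),
            "intensity_global": slice(353, 366),
            "glih": slice(366, 371),
            "hog": slice(371, 452),
        }
        counts = {
            "pca": 10, "glcm": 16, "gabor": 160, "lbp": 64, "laws": 28,
            "window": 75, "intensity_global": 13, "glih": 5, "hog": 81,
        }
        assert sum(counts.values()) == 452
        for cat, sl in self.category_slices.items():
            assert sl.stop - sl.start == counts[cat], cat
        assert len(names) == 452

    def __len__(self) -> int:
        return 452

    def category_counts(self) -> dict[str, int]:
        return {
            cat: sl.stop - sl.start for cat, sl in self.category_slices.items()
        }


REGISTRY = FeatureRegistry()


def eligible_columns(
    contour: ILMContour, shape: tuple[int, int], geom: WindowGeometry
) -> np.ndarray:
    """Boolean mask of columns whose full window fits inside the scan."""
    return np.array(
        [geom.fits(contour.rows[c], c, shape) for c in range(contour.width)]
    )


def extract_window(
    scan: BScan, contour: ILMContour, column: int, geom: WindowGeometry
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Cut the rectangular window and its five sub-patches at one column.

    Raises :class:`WindowOutOfBounds` when the window would be clipped by
    an image border (the caller excludes such points from sampling).
    """
    if not geom.fits(contour.rows[column], column, scan.pixels.shape):
        raise WindowOutOfBounds(
            f"window at column {column} clips the image border"
        )
    top, left = geom.bounds(contour.rows[column], column)
    s = geom.sub_side
    window = scan.pixels[top : top + geom.win_height, left : left + s]
    subs = [window[i * s : (i + 1) * s] for i in range(geom.n_sub)]
    return window, subs


# ---------------------------------------------------------------------------
# per-category feature computations


def _hist_entropy_energy(values: np.ndarray) -> tuple[float, float]:
    hist, _ = np.histogram(values, bins=_ENTROPY_BINS, range=(0.0, 1.0))
    p = hist / max(values.size, 1)
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    energy = float((p**2).sum())
    return entropy, energy


def _stat_block(values: np.ndarray) -> list[float]:
    """mean, std, min, max, median, range, skew, kurtosis, entropy, energy.

    Skewness and (excess) kurtosis are the biased population moments; both
    are defined as 0 on constant patches.
    """
    v = values.ravel()
    entropy, energy = _hist_entropy_energy(v)
    mean = v.mean()
    d = v - mean
    m2 = float((d**2).mean())
    if m2 > 1e-18:
        skew = float((d**3).mean() / m2**1.5)
        kurt = float((d**4).mean() / m2**2 - 3.0)
    else:
        skew = kurt = 0.0
    return [
        float(mean),
        float(np.sqrt(m2)),
        float(v.min()),
        float(v.max()),
        float(np.median(v)),
        float(v.max() - v.min()),
        skew,
        kurt,
        entropy,
        energy,
    ]


def _hist5(values: np.ndarray) -> np.ndarray:
    hist, _ = np.histogram(values, bins=5, range=(0.0, 1.0))
    return hist / max(values.size, 1)


def glcm_features(window: np.ndarray) -> np.ndarray:
    q = np.clip((window * GLCM_LEVELS).astype(int), 0, GLCM_LEVELS - 1)
    mat = graycomatrix(
        q.astype(np.uint8),
        distances=[1],
        angles=list(GLCM_ANGLES),
        levels=GLCM_LEVELS,
        normed=True,
    )
    vals = [graycoprops(mat, p)[0] for p in GLCM_PROPS]  # each (4,)
    return np.nan_to_num(np.concatenate(vals), nan=0.0)


def lbp_histogram(codes: np.ndarray) -> np.ndarray:
    hist = np.bincount(codes.ravel().astype(int), minlength=2**LBP_P)
    return hist / max(codes.size, 1)


def window_features(subs: list[np.ndarray]) -> np.ndarray:
    out: list[float] = []
    for sub in subs:
        out.extend(_stat_block(sub))
        out.extend(_hist5(sub))
    return np.asarray(out)


def intensity_global_features(window: np.ndarray) -> np.ndarray:
    v = window.ravel()
    return np.asarray(
        _stat_block(v)
        + [
            float(np.percentile(v, 25)),
            float(np.percentile(v, 75)),
            float(v.var()),
        ]
    )


def glih(window: np.ndarray) -> np.ndarray:
    return _hist5(window)


def hog_features(window: np.ndarray) -> np.ndarray:
    h, w = window.shape
    return hog(
        window,
        orientations=9,
        pixels_per_cell=(h // 3, w // 3),
        cells_per_block=(3, 3),
        block_norm="L2",
        feature_vector=True,
    )


def _gabor_kernels() -> list[np.ndarray]:
    from skimage.filters import gabor_kernel

    kernels = []
    for wavelength in GABOR_WAVELENGTHS:
        for o in range(N_ORIENTATIONS):
            theta = np.pi * o / N_ORIENTATIONS
            kernels.append(gabor_kernel(1.0 / wavelength, theta=theta))
    return kernels


_GABOR_KERNELS = _gabor_kernels()


def _laws_kernels() -> list[tuple[str, np.ndarray, np.ndarray | None]]:
    """(name, kernel_a, kernel_b_or_None) — pairs average |resp_a|, |resp_b|."""
    out = []
    for a, b in _LAWS_PAIRS:
        ka = np.outer(_LAWS_1D[a], _LAWS_1D[b])
        kb = np.outer(_LAWS_1D[b], _LAWS_1D[a])
        out.append((f"{a}{b}", ka, kb))
    for k in _LAWS_DIAG:
        out.append((f"{k}{k}", np.outer(_LAWS_1D[k], _LAWS_1D[k]), None))
    return out


_LAWS_KERNELS = _laws_kernels()


class ScanFeatureExtractor:
    """Computes feature vectors for ILM points of a single B-scan.

    Full-scan response maps (Gabor magnitudes, Laws texture energies, LBP
    codes) are computed once on construction and pooled per window; the
    remaining categories operate on the window patch directly.
    """

    def __init__(
        self,
        scan: BScan,
        geom: WindowGeometry | None = None,
        pca_basis: PCABasis | None = None,
    ) -> None:
        self.scan = scan
        self.geom = geom or WindowGeometry()
        self.pca_basis = pca_basis
        px = scan.pixels
        self._gabor_maps = [
            np.abs(fftconvolve(px, k, mode="same")) for k in _GABOR_KERNELS
        ]
        self._laws_maps = []
        for _name, ka, kb in _LAWS_KERNELS:
            resp = np.abs(fftconvolve(px, ka, mode="same"))
            if kb is not None:
                resp = 0.5 * (resp + np.abs(fftconvolve(px, kb, mode="same")))
            self._laws_maps.append(resp)
        # LBP on the 8-bit quantization: integer comparisons are stable
        px8 = np.clip(np.rint(px * 255.0), 0, 255).astype(np.uint8)
        self._lbp_codes = local_binary_pattern(
            px8, LBP_P, LBP_R, method="default"
        )

    def eligible(self, contour: ILMContour) -> np.ndarray:
        return eligible_columns(contour, self.scan.pixels.shape, self.geom)

    def features_at(self, contour: ILMContour, column: int) -> np.ndarray:
        """The full 452-vector at one ILM point (fixed category order)."""
        if self.pca_basis is None:
            raise ConfigurationError(
                "PCA basis not fitted: call fit_pca_basis on training windows "
                "before extracting features"
            )
        window, subs = extract_window(self.scan, contour, column, self.geom)
        top, left = self.geom.bounds(contour.rows[column], column)
        s = self.geom.sub_side
        rows = slice(top, top + self.geom.win_height)
        cols = slice(left, left + s)

        gabor_vals = np.empty(len(self._gabor_maps) * N_SUB)
        for gi, gmap in enumerate(self._gabor_maps):
            patch = gmap[rows, cols]
            for si in range(N_SUB):
                gabor_vals[gi * N_SUB + si] = patch[
                    si * s : (si + 1) * s
                ].mean()

        laws_vals = np.empty(len(self._laws_maps) * 2)
        for li, lmap in enumerate(self._laws_maps):
            patch = lmap[rows, cols]
            laws_vals[2 * li] = patch.mean()
            laws_vals[2 * li + 1] = patch.std()

        parts = [
            self.pca_basis.project(window),
            glcm_features(window),
            gabor_vals,
            lbp_histogram(self._lbp_codes[rows, cols]),
            laws_vals,
            window_features(subs),
            intensity_global_features(window),
            glih(window),
            hog_features(window),
        ]
        vec = np.concatenate(parts)
        assert vec.size == len(REGISTRY)
        return np.nan_to_num(vec, nan=0.0, posinf=0.0, neginf=0.0)

    def feature_matrix(
        self, contour: ILMContour, columns
    ) -> np.ndarray:
        return np.vstack([self.features_at(contour, c) for c in columns])


def extract_features(
    scan: BScan,
    contour: ILMContour,
    column: int,
    geom: WindowGeometry | None = None,
    pca_basis: PCABasis | None = None,
) -> np.ndarray:
    """One-shot feature vector at a single point.

    Convenience wrapper; use :class:`ScanFeatureExtractor` when extracting
    many points of the same scan (it caches the full-scan response maps).
    """
    return ScanFeatureExtractor(scan, geom, pca_basis).features_at(
        contour, column
    )
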