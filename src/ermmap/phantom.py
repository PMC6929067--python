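"""Synthetic OCT phantom volumes with known ILM geometry and ERM truth.

The generator emulates the gross appearance of a macular SD-OCT stack: a
dark vitreous above a bright retinal band whose top surface (the ILM) dips
parabolically at the fovea and undulates slowly from slice to slice,
multiplicative speckle, and an optional thin hyper-reflective band — the
epiretinal membrane — sitting on or slightly above the ILM over a contiguous
lateral extent. Every generated pixel of ERM is recorded in a per-pixel
en-face ground-truth map so all downstream stages can be scored without
clinical data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .core import ConfigurationError, DataError, ERMMap, ILMContour, OCTVolume

__all__ = [
    "PhantomSpec",
    "PhantomVolume",
    "generate_phantom",
    "write_phantom",
    "read_manifest_spec",
]


@dataclass
class PhantomSpec:
    """Geometry, intensity and noise parameters of a synthetic OCT volume.

    ``erm_regions`` is a list of ``(slice_start, slice_end, col_start,
    col_end, detach_px)`` half-open extents; within each, a 1-3 px thick
    band at ``erm_level`` is drawn ``detach_px`` above the ILM surface
    (0 = attached). Intensities are mean 8-bit levels with
    ``erm_level > tissue_level > vitreous_level`` (the ERM is
    hyper-reflective, the vitreous is darkest).
    """

    n_slices: int = 32
    height: int = 160
    width: int = 128
    ilm_baseline_row: int = 55
    ilm_curvature_amp: float = 12.0
    ilm_wobble_amp: float = 2.0
    retina_thickness: int = 70
    tissue_level: float = 120.0
    vitreous_level: float = 25.0
    erm_level: float = 230.0
    speckle_sigma: float = 0.08
    erm_regions: list[tuple[int, int, int, int, int]] = field(default_factory=list)
    rng_seed: int = 0

    MAX_ERM_THICKNESS = 3

    def validate(self) -> None:
        if self.n_slices < 1 or self.height < 1 or self.width < 1:
            raise ConfigurationError("n_slices, height and width must be positive")
        if not (self.erm_level > self.tissue_level > self.vitreous_level):
            raise ConfigurationError(
                "intensity ordering violated: require erm_level > tissue_level "
                f"> vitreous_level, got {self.erm_level}/{self.tissue_level}/"
                f"{self.vitreous_level}"
            )
        if self.speckle_sigma < 0:
            raise ConfigurationError("speckle_sigma must be >= 0")
        swing = abs(self.ilm_curvature_amp) + abs(self.ilm_wobble_amp)
        if self.ilm_baseline_row - abs(self.ilm_wobble_amp) < 0:
            raise ConfigurationError(
                "ilm_baseline_row too small: surface wobble would leave the image"
            )
        if self.ilm_baseline_row + swing >= self.height - self.retina_thickness:
            raise ConfigurationError(
                "ilm_baseline_row + curvature/wobble swing exceeds "
                "height - retina_thickness: retina would not fit below the ILM"
            )
        for k, reg in enumerate(self.erm_regions):
            if len(reg) != 5:
                raise ConfigurationError(
                    f"erm_regions[{k}] must be a 5-tuple "
                    "(slice_start, slice_end, col_start, col_end, detach_px)"
                )
            s0, s1, c0, c1, detach = reg
            if not (0 <= s0 < s1 <= self.n_slices):
                raise ConfigurationError(
                    f"erm_regions[{k}] slice range [{s0}, {s1}) outside "
                    f"[0, {self.n_slices})"
                )
            if not (0 <= c0 < c1 <= self.width):
                raise ConfigurationError(
                    f"erm_regions[{k}] column range [{c0}, {c1}) outside "
                    f"[0, {self.width})"
                )
            if detach < 0:
                raise ConfigurationError(f"erm_regions[{k}] detach_px must be >= 0")
            # the thickest band at maximum detachment must stay in the image
            min_top = (
                self.ilm_baseline_row
                - abs(self.ilm_wobble_amp)
                - detach
                - self.MAX_ERM_THICKNESS
            )
            if min_top < 0:
                raise ConfigurationError(
                    f"erm_regions[{k}]: detach_px={detach} would push the ERM "
                    "band above row 0"
                )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["erm_regions"] = [list(r) for r in self.erm_regions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["erm_regions"] = [tuple(r) for r in d.get("erm_regions", [])]
        return cls(**d)


@dataclass
class PhantomVolume:
    """A generated volume plus its ground truth.

    ``slices``: (n_slices, height, width) uint8 stack; ``true_ilm``:
    (n_slices, width) float row coordinates; ``true_map``: binary en-face
    ERM ground truth; ``spec``: the generating parameters.
    """

    slices: np.ndarray
    true_ilm: np.ndarray
    true_map: ERMMap
    spec: PhantomSpec

    def __post_init__(self) -> None:
        if not (
            len(self.slices) == len(self.true_ilm) == self.true_map.n_slices
        ):
            raise DataError("slices, true_ilm and true_map disagree on slice count")

    def volume(self, volume_id: str = "phantom") -> OCTVolume:
        """View as an OCTVolume with intensities scaled to [0, 1]."""
        return OCTVolume(self.slices.astype(float) / 255.0, volume_id=volume_id)

    def contours(self) -> list[ILMContour]:
        return [
            ILMContour(rows, slice_index=i) for i, rows in enumerate(self.true_ilm)
        ]


def _ilm_surface(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """True ILM row per (slice, column): foveal parabola + smooth wobble."""
    w, n = spec.width, spec.n_slices
    u = np.linspace(-1.0, 1.0, w) if w > 1 else np.zeros(1)
    dip = spec.ilm_curvature_amp * (1.0 - u**2)  # deepest at the center
    rows = np.empty((n, w))
    # one lateral frequency/phase for the whole volume, drifting across slices
    freq = rng.uniform(1.0, 2.0)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    slice_phase = rng.uniform(0.1, 0.4)
    for s in range(n):
        wob = spec.ilm_wobble_amp * np.sin(
            2.0 * np.pi * freq * np.arange(w) / max(w, 1)
            + phase
            + slice_phase * s
        )
        rows[s] = spec.ilm_baseline_row + dip + wob
    return rows


def generate_phantom(spec: PhantomSpec) -> PhantomVolume:
    """Render a synthetic OCT volume from ``spec``.

    Deterministic for a fixed ``rng_seed``. Each B-scan has vitreous above
    the ILM row, retinal tissue below it, and an ERM band exactly where
    ``erm_regions`` dictates; ``true_map[s, c] == 1`` iff (s, c) lies inside
    some region.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    true_ilm = _ilm_surface(spec, rng)
    n, h, w = spec.n_slices, spec.height, spec.width

    stack = np.full((n, h, w), spec.vitreous_level, dtype=float)
    rows_grid = np.arange(h)[:, None]
    ilm_int = np.rint(true_ilm).astype(int)
    for s in range(n):
        top = ilm_int[s][None, :]
        in_retina = (rows_grid >= top) & (rows_grid < top + spec.retina_thickness)
        stack[s][in_retina] = spec.tissue_level

    true_map = np.zeros((n, w), dtype=np.uint8)
    for reg in spec.erm_regions:
        s0, s1, c0, c1, detach = reg
        thickness = int(rng.integers(1, PhantomSpec.MAX_ERM_THICKNESS + 1))
        for s in range(s0, s1):
            band_top = ilm_int[s, c0:c1] - detach - thickness
            for t in range(thickness):
                stack[s, band_top + t, np.arange(c0, c1)] = spec.erm_level
        true_map[s0:s1, c0:c1] = 1

    if spec.speckle_sigma > 0:
        stack *= 1.0 + spec.speckle_sigma * rng.standard_normal(stack.shape)
    stack = np.clip(np.rint(stack), 0, 255).astype(np.uint8)

    return PhantomVolume(
        slices=stack,
        true_ilm=true_ilm,
        true_map=ERMMap(true_map, provenance="truth"),
        spec=spec,
    )


def write_phantom(vol: PhantomVolume, dir_path) -> dict:
    """Save a phantom as numbered 8-bit PNG slices plus ground truth.

    Writes ``slice_####.png``, ``true_map.png`` (0/255), ``true_ilm.csv``
    (slice, column, row) and ``manifest.json`` embedding the generating
    spec; returns the manifest dict.
    """
    out = Path(dir_path)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise DataError(f"cannot create output directory {out}: {exc}") from exc

    files = []
    for i, img in enumerate(vol.slices):
        name = f"slice_{i:04d}.png"
        iio.imwrite(out / name, img)
        files.append(name)
    iio.imwrite(out / "true_map.png", vol.true_map.grid * np.uint8(255))
    with open(out / "true_ilm.csv", "w") as fh:
        fh.write("slice,column,row\n")
        for s in range(vol.true_ilm.shape[0]):
            for c in range(vol.true_ilm.shape[1]):
                fh.write(f"{s},{c},{vol.true_ilm[s, c]:.4f}\n")
    manifest = {
        "n_slices": len(files),
        "slice_files": files,
        "true_map": "true_map.png",
        "true_ilm": "true_ilm.csv",
        "spec": vol.spec.to_dict(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_manifest_spec(dir_path) -> PhantomSpec:
    """Recover the generating spec embedded in a phantom directory manifest."""
    path = Path(dir_path) / "manifest.json"
    if not path.exists():
        raise DataError(f"no manifest.json in {dir_path}")
    with open(path) as fh:
        manifest = json.load(fh)
    return PhantomSpec.from_dict(manifest["spec"])
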