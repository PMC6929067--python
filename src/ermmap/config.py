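"""Run configuration: every stage tunable with reproducible defaults.

A ``RunConfig`` can be loaded from YAML or JSON; missing sections or fields
fall back to the package defaults (and the fallback is logged), so a config
file only needs to state what it overrides. All randomness in a run funnels
through the single ``seed``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import ConfigurationError
from .features import WindowGeometry
from .mapping import PostprocessParams
from .snake import SnakeParams

logger = logging.getLogger("ermmap")

__all__ = ["StudySpec", "RunConfig"]


@dataclass
class StudySpec:
    """Shape of the built-in synthetic phantom study."""

    n_train: int = 5
    n_test_erm: int = 5
    n_test_clean: int = 3
    n_slices: int = 32
    height: int = 160
    width: int = 128
    speckle_sigma: float = 0.08


@dataclass
class RunConfig:
    """All tunables of the end-to-end pipeline."""

    seed: int = 0
    snake: SnakeParams = field(default_factory=SnakeParams)
    window: WindowGeometry = field(default_factory=WindowGeometry)
    study: StudySpec = field(default_factory=StudySpec)
    n_training_samples: int = 800
    feature_count_grid: list[int] = field(
        default_factory=lambda: list(range(20, 201, 20))
    )
    classifiers: list[str] = field(
        default_factory=lambda: ["RF", "SVM", "kNN-2", "kNN-6", "kNN-8"]
    )
    refine_radius: int = 0  # unit-step refinement around the coarse best k
    svm_hyper: dict = field(default_factory=lambda: {"C": 10.0, "gamma": "scale"})
    postprocess_min_areas: list[int] = field(
        default_factory=lambda: [0, 10, 25, 50, 100, 200]
    )
    postprocess_radii: list[int] = field(
        default_factory=lambda: [0, 1, 2, 3, 5, 7]
    )
    connectivity: int = 8

    def postprocess_grid(self) -> list[PostprocessParams]:
        return [
            PostprocessParams(a, r, self.connectivity)
            for a in self.postprocess_min_areas
            for r in self.postprocess_radii
        ]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        kwargs: dict = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                logger.info("config: %s missing, default applied", f.name)
                continue
            val = d.pop(f.name)
            if f.name == "snake":
                val = SnakeParams(**val)
            elif f.name == "window":
                val = WindowGeometry(**val)
            elif f.name == "study":
                val = StudySpec(**val)
            kwargs[f.name] = val
        if d:
            raise ConfigurationError(f"unknown config keys: {sorted(d)}")
        return cls(**kwargs)

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        text = path.read_text()
        if path.suffix in (".yml", ".yaml"):
            data = yaml.safe_load(text)
        elif path.suffix == ".json":
            data = json.loads(text)
        else:
            raise ConfigurationError(
                f"unsupported config format {path.suffix!r} (use YAML or JSON)"
            )
        return cls.from_dict(data)

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            if path.suffix in (".yml", ".yaml"):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
            else:
                json.dump(self.to_dict(), fh, indent=2)
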