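"""End-to-end orchestration of the ERM mapping pipeline.

The full chain is: ILM segmentation -> feature extraction -> SURF ranking
-> feature-count sweep and classifier selection -> per-slice prediction ->
en-face map assembly -> morphological refinement -> metrics. The built-in
synthetic study runs the whole chain on phantom volumes (a training set
with ERM, ERM test volumes, and ERM-free test volumes) so the pipeline is
exercised and scored without clinical data.

Post-processing parameters are grid-optimized over the evaluation volumes'
predicted maps (the protocol under which the refinement can only help the
mean Dice, since the identity transform is part of the search grid).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classify import (
    TrainedModel,
    predict_points,
    refine_feature_count,
    sample_training_set,
    sweep_feature_counts,
    train_model,
)
from .config import RunConfig
from .core import AnnotatedVolume, ERMMap, StageError
from .io import save_map
from .mapping import build_map, optimize_postprocess, refine_map
from .metrics import aggregate, compute_metrics, confusion
from .phantom import PhantomSpec, generate_phantom
from .selection import surf_rank
from .snake import segment_volume

logger = logging.getLogger("ermmap")

__all__ = ["PipelineRun", "make_study", "run_pipeline", "predict_volume_map"]


@dataclass
class PipelineRun:
    """Record of one pipeline execution: config, outputs and timings."""

    config: RunConfig
    summary: dict
    timings: dict[str, float] = field(default_factory=dict)
    artifacts: dict[str, str] = field(default_factory=dict)


def random_erm_regions(
    rng: np.random.Generator, n_slices: int, width: int, n_regions: int | None = None
) -> list[tuple[int, int, int, int, int]]:
    """Draw 1-2 contiguous ERM extents covering a plausible macular patch."""
    if n_regions is None:
        n_regions = int(rng.integers(1, 3))
    regions = []
    for _ in range(n_regions):
        ds = int(rng.integers(n_slices // 3, max(n_slices * 2 // 3, n_slices // 3 + 1)))
        dc = int(rng.integers(width // 3, max(width * 2 // 3, width // 3 + 1)))
        s0 = int(rng.integers(0, n_slices - ds + 1))
        c0 = int(rng.integers(0, width - dc + 1))
        detach = int(rng.choice([0, 0, 0, 1, 2]))
        regions.append((s0, s0 + ds, c0, c0 + dc, detach))
    return regions


def make_study(config: RunConfig):
    """Generate and segment the synthetic study volumes.

    Returns three lists of :class:`AnnotatedVolume` (training with ERM,
    test with ERM, test ERM-free); contours come from the snake, truth
    from the generator.
    """
    st = config.study
    rng = np.random.default_rng(config.seed)

    def build(tag: str, count: int, with_erm: bool) -> list[AnnotatedVolume]:
        out = []
        for i in range(count):
            regions = (
                random_erm_regions(rng, st.n_slices, st.width) if with_erm else []
            )
            spec = PhantomSpec(
                n_slices=st.n_slices,
                height=st.height,
                width=st.width,
                speckle_sigma=st.speckle_sigma,
                erm_regions=regions,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
            )
            phantom = generate_phantom(spec)
            vol = phantom.volume(volume_id=f"{tag}_{i:02d}")
            contours = segment_volume(vol, config.snake)
            out.append(
                AnnotatedVolume(
                    volume=vol,
                    contours=contours,
                    truth=phantom.true_map,
                    true_ilm=phantom.true_ilm,
                )
            )
        return out

    t0 = time.perf_counter()
    train = build("train", st.n_train, with_erm=True)
    test_erm = build("test_erm", st.n_test_erm, with_erm=True)
    test_clean = build("test_clean", st.n_test_clean, with_erm=False)
    logger.info("study generation + segmentation: %.1fs", time.perf_counter() - t0)
    return train, test_erm, test_clean


def predict_volume_map(model: TrainedModel, av: AnnotatedVolume) -> ERMMap:
    """Predict every slice of a volume and assemble the raw en-face map."""
    vectors = [
        predict_points(model, av.volume.scan(i), av.contours[i])
        for i in range(av.volume.n_slices)
    ]
    return build_map(vectors)


def run_pipeline(config: RunConfig, out_dir=None) -> PipelineRun:
    """Execute the full synthetic study end-to-end.

    Writes maps and a JSON summary under ``out_dir`` when given. A stage
    failure is re-raised as :class:`StageError` naming the stage; outputs
    produced before the failure are retained for debugging.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    artifacts: dict[str, str] = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s ...", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(f"stage {name!r} failed: {exc}") from exc
                logger.info("stage %s done in %.1fs", name, timings[name])

        return _Timer()

    with stage("study"):
        train, test_erm, test_clean = make_study(config)

    with stage("train"):
        data, basis = sample_training_set(
            train, config.n_training_samples, seed=config.seed, geom=config.window
        )
        ranking = surf_rank(data)
        sweep = sweep_feature_counts(
            data,
            ranking,
            ks=[k for k in config.feature_count_grid if k <= data.n_features],
            kinds=config.classifiers,
            seed=config.seed,
            hyper=config.svm_hyper,
        )
        best_kind = max(sweep.best_accuracy, key=sweep.best_accuracy.get)
        best_k = sweep.best_k[best_kind]
        if config.refine_radius > 0:
            best_k, _ = refine_feature_count(
                data,
                ranking,
                best_kind,
                best_k,
                radius=config.refine_radius,
                seed=config.seed,
                hyper=config.svm_hyper,
            )
        model = train_model(
            data,
            ranking,
            best_k,
            best_kind,
            basis,
            config.window,
            seed=config.seed,
            hyper=config.svm_hyper,
            metadata={"cv_accuracy": sweep.best_accuracy[best_kind]},
        )

    with stage("predict"):
        test_raw = [
            predict_volume_map(model, av) for av in test_erm + test_clean
        ]

    with stage("refine"):
        params, opt_dice = optimize_postprocess(
            test_raw,
            [av.truth for av in test_erm + test_clean],
            grid=config.postprocess_grid(),
        )
        test_refined = [refine_map(m, params) for m in test_raw]

    with stage("evaluate"):
        reports = {"raw": [], "refined": []}
        test_avols = test_erm + test_clean
        for av, raw, ref in zip(test_avols, test_raw, test_refined):
            reports["raw"].append(
                compute_metrics(
                    confusion(raw, av.truth), av.volume.volume_id, "classification"
                )
            )
            reports["refined"].append(
                compute_metrics(
                    confusion(ref, av.truth), av.volume.volume_id, "postprocess"
                )
            )
        n_erm = len(test_erm)
        summary = {
            "classifier": model.classifier_kind,
            "n_features": int(model.metadata["k_features"]),
            "cv_accuracy": float(model.metadata["cv_accuracy"]),
            "sweep_table": {
                kind: {int(k): float(v) for k, v in row.items()}
                for kind, row in sweep.table.iterrows()
            },
            "postprocess_params": {
                "min_area": params.min_area,
                "closing_radius": params.closing_radius,
            },
            "postprocess_opt_mean_dice": float(opt_dice),
            "erm_volumes": {
                "raw": aggregate(reports["raw"][:n_erm]),
                "refined": aggregate(reports["refined"][:n_erm]),
            },
            "clean_volumes": {
                "raw": aggregate(reports["raw"][n_erm:]),
                "refined": aggregate(reports["refined"][n_erm:]),
            },
        }

    if out is not None:
        with stage("write"):
            for av, raw, ref in zip(test_avols, test_raw, test_refined):
                vid = av.volume.volume_id
                save_map(raw, out / "maps" / f"{vid}_raw.png")
                save_map(ref, out / "maps" / f"{vid}_refined.png")
                save_map(av.truth, out / "maps" / f"{vid}_truth.png")
                artifacts[vid] = str(out / "maps")
            summary_path = out / "summary.json"
            with open(summary_path, "w") as fh:
                json.dump(
                    {
                        "summary": summary,
                        "timings": timings,
                        "config": dataclasses.asdict(config),
                    },
                    fh,
                    indent=2,
                )
            artifacts["summary"] = str(summary_path)

    return PipelineRun(
        config=config, summary=summary, timings=timings, artifacts=artifacts
    )
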