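"""Shared fixtures: small phantoms for unit tests and one full synthetic
study (session-scoped, since segmentation + prediction dominate runtime)."""

import numpy as np
import pytest

from ermmap.config import RunConfig
from ermmap.core import AnnotatedVolume
from ermmap.phantom import PhantomSpec, generate_phantom
from ermmap.pipeline import run_pipeline
from ermmap.snake import segment_volume


@pytest.fixture(scope="session")
def flat_phantom():
    """Noiseless phantom with a perfectly flat ILM at the baseline row."""
    spec = PhantomSpec(
        n_slices=3,
        ilm_curvature_amp=0.0,
        ilm_wobble_amp=0.0,
        speckle_sigma=0.0,
        rng_seed=11,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def parabolic_phantom():
    """Noiseless phantom with the default foveal dip and wobble."""
    spec = PhantomSpec(n_slices=3, speckle_sigma=0.0, rng_seed=12)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def erm_phantom():
    """Noiseless phantom with one attached ERM band over half the width."""
    spec = PhantomSpec(
        n_slices=6,
        speckle_sigma=0.0,
        erm_regions=[(1, 5, 30, 95, 0)],
        rng_seed=13,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def annotated_erm(erm_phantom):
    """The ERM phantom segmented by the snake, truth attached."""
    vol = erm_phantom.volume("erm_fixture")
    contours = segment_volume(vol)
    return AnnotatedVolume(
        volume=vol,
        contours=contours,
        truth=erm_phantom.true_map,
        true_ilm=erm_phantom.true_ilm,
    )


@pytest.fixture(scope="session")
def study_run():
    """The reduced synthetic study, run end-to-end once with a fixed seed.

    5 training + 5 ERM test + 3 ERM-free test volumes of 32 slices x
    128 px; 800 balanced training samples; feature-count sweep over all
    five classifier configurations.
    """
    return run_pipeline(RunConfig(seed=1))
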