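"""Shared fixtures: synthetic scenes reused across test modules."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from microquant.benchmark import truth_background
from microquant.pipeline import RunConfig
from microquant.segment import segment_field
from microquant.synthetic import SceneParams, generate_scene


@pytest.fixture(scope="session")
def small_params() -> SceneParams:
    """A compact two-cell field used by fast unit tests (no flagged cells)."""
    return SceneParams(
        field_size=(384, 384),
        n_cells=2,
        fraction_apoptotic=0.0,
        fraction_dim=0.0,
        fraction_edge=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_scene(small_params):
    return generate_scene(small_params)


@pytest.fixture(scope="session")
def small_segmentation(small_scene):
    image, _ = small_scene
    return segment_field(image)


@pytest.fixture(scope="session")
def small_background(small_params):
    return truth_background(small_params, RunConfig())


@pytest.fixture(scope="session")
def default_scene():
    """One full-size default-parameter scene (flags possible)."""
    return generate_scene(replace(SceneParams(), seed=42))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
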