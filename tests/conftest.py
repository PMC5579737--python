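"""Shared fixtures: synthetic scenes are rendered once per session."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from footarch.arch_params import measure
from footarch.synthetic_foot import generate_scene, preset_params


@pytest.fixture(scope="session")
def clean_scene():
    return generate_scene(preset_params("clean"))


@pytest.fixture(scope="session")
def flat_scene():
    return generate_scene(preset_params("flat"))


@pytest.fixture(scope="session")
def tilted_scene():
    return generate_scene(preset_params("tilted"))


@pytest.fixture(scope="session")
def noisy_scenes():
    return [generate_scene(preset_params("noisy", seed=s))
            for s in (11, 12, 13)]


@pytest.fixture(scope="session")
def clean_measurement(clean_scene):
    frame, gt = clean_scene
    return measure(frame, gt.toe2_center, seed=0)


@pytest.fixture(scope="session")
def noisy_measurements(noisy_scenes):
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for frame, gt in noisy_scenes:
            out.append(measure(frame, gt.toe2_center, seed=0))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
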