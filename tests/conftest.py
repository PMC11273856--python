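"""Shared fixtures: one default synthetic eye processed through the chain.

The expensive artifacts (rendered volume, enhanced volume, segmentation) are
session-scoped so every test module reuses the same objects.
"""

from __future__ import annotations

import numpy as np
import pytest

from choromet.enhancement import enhance_volume
from choromet.morphometry import Calibration
from choromet.segmentation import segment_volume
from choromet.synthetic_data import EyeGeometryConfig, NoiseConfig, generate_eye, render_volume


@pytest.fixture(scope="session")
def eye_config() -> EyeGeometryConfig:
    return EyeGeometryConfig()


@pytest.fixture(scope="session")
def eye_truth(eye_config):
    return generate_eye(eye_config, seed=1)


@pytest.fixture(scope="session")
def eye_volume(eye_truth):
    return render_volume(eye_truth, NoiseConfig(seed=1))


@pytest.fixture(scope="session")
def enhanced_volume(eye_volume):
    return enhance_volume(eye_volume)


@pytest.fixture(scope="session")
def segmented_surfaces(enhanced_volume):
    return segment_volume(enhanced_volume)


@pytest.fixture(scope="session")
def calibration(eye_volume) -> Calibration:
    return Calibration.from_volume(eye_volume)


@pytest.fixture(scope="session")
def noisefree_volume(eye_truth):
    """Same eye rendered without speckle (shape -> infinity limit)."""
    return render_volume(
        eye_truth, NoiseConfig(speckle_shape=1e9, attenuation_coeff=0.5, seed=1)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
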