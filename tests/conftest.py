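"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from retoct.config import PhantomConfig
from retoct import phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_config():
    """Flat, noiseless, pit-free phantom — analytic ground truth everywhere."""
    return PhantomConfig(
        volume_shape=(24, 32, 256),
        fov_mm=(0.24, 0.32, 0.64),
        curvature_coeffs=((0.0,),),
        onh_radius_um=0.0,
        speckle_shape=float("inf"),
        vessel_density=0,
    )


@pytest.fixture
def desk_config():
    """Default desk-scale phantom (curved, ONH pit, speckle, vessels)."""
    return PhantomConfig()


@pytest.fixture
def flat_scene(flat_config, rng):
    surfaces = phantom.make_geometry(flat_config)
    volume, labels = phantom.render_volume(surfaces, flat_config, rng)
    return flat_config, surfaces, volume, labels


@pytest.fixture
def desk_scene(desk_config, rng):
    surfaces = phantom.make_geometry(desk_config)
    volume, labels = phantom.render_volume(surfaces, desk_config, rng)
    return desk_config, surfaces, volume, labels
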