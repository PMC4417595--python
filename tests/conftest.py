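"""Shared fixtures: phantoms and one segmented volume, built once per session."""

import numpy as np
import pytest

from retidiff.phantom import PhantomConfig, generate_phantom
from retidiff.segmentation import segment_volume


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free default phantom: piecewise-constant layer reflectivities."""
    cfg = PhantomConfig(speckle_sigma=0.0)
    volume, truth = generate_phantom(cfg)
    return cfg, volume, truth


@pytest.fixture(scope="session")
def speckled_phantom():
    """Default phantom with multiplicative speckle (sigma = 0.1)."""
    cfg = PhantomConfig()
    volume, truth = generate_phantom(cfg)
    return cfg, volume, truth


@pytest.fixture(scope="session")
def segmented(speckled_phantom):
    """Full two-stage segmentation of the speckled phantom (expensive)."""
    _, volume, truth = speckled_phantom
    result = segment_volume(volume)
    return volume, truth, result


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
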