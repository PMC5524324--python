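"""Shared fixtures: grids, atlases and phantom images at CI scale."""

from __future__ import annotations

import numpy as np
import pytest

from tbmpipe.core import GridSpec
from tbmpipe.phantom import build_atlas, default_tissue_params, simulate_t2_image


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    """The 64x64x48 CI grid at acquisition spacing."""
    return GridSpec(shape=(64, 64, 48))


@pytest.fixture(scope="session")
def mini_grid() -> GridSpec:
    """Smallest grid on which the full atlas is still placeable."""
    return GridSpec(shape=(48, 48, 36))


@pytest.fixture(scope="session")
def atlas(small_grid):
    return build_atlas(small_grid)


@pytest.fixture(scope="session")
def mini_atlas(mini_grid):
    return build_atlas(mini_grid)


@pytest.fixture(scope="session")
def t2_clean(atlas):
    """Noise-free T2-like template image on the CI grid."""
    return simulate_t2_image(atlas, default_tissue_params(noise_sd=0.0), seed=0)


@pytest.fixture(scope="session")
def mini_t2_clean(mini_atlas):
    return simulate_t2_image(mini_atlas, default_tissue_params(noise_sd=0.0), seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
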