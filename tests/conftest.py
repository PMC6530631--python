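"""Shared fixtures: reduced-volume scaffolds that keep the reference
densities and rules but shrink the base area, so geometry-sensitive
behaviour is preserved at test-friendly size."""

import logging

import numpy as np
import pytest

from cerescaffold.config import default_config, scale_config
from cerescaffold.connectivity import build_connectome
from cerescaffold.placement import place_all

logging.getLogger("cerescaffold").setLevel(logging.ERROR)

TEST_SEED = 1


@pytest.fixture(scope="session")
def cfg_ref():
    return default_config(TEST_SEED)


@pytest.fixture(scope="session")
def cfg_small(cfg_ref):
    """~10% of the reference area: ~9k granule cells, 1 DCN cell."""
    return scale_config(cfg_ref, 0.1)


@pytest.fixture(scope="session")
def placement_small(cfg_small):
    return place_all(cfg_small, seed=TEST_SEED)


@pytest.fixture(scope="session")
def connectome_small(cfg_small, placement_small):
    return build_connectome(placement_small, cfg_small, seed=TEST_SEED)


@pytest.fixture(scope="session")
def cfg_tiny(cfg_ref):
    """~2.5% of the reference area for the cheapest geometry tests."""
    return scale_config(cfg_ref, 0.025)


@pytest.fixture(scope="session")
def placement_tiny(cfg_tiny):
    return place_all(cfg_tiny, seed=TEST_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(TEST_SEED)
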