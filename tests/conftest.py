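"""Shared fixtures: the expensive simulation grid is built once per session."""

import numpy as np
import pytest

from npcmorph import baseline as bl

MASTER_SEED = 1234


@pytest.fixture(scope="session")
def master_seed():
    return MASTER_SEED


@pytest.fixture(scope="session")
def pipeline_delta(master_seed):
    """Coverage correction calibrated for the default simulated pipeline."""
    return bl.calibrate_delta(seed=master_seed)


@pytest.fixture(scope="session")
def null_grid(master_seed, pipeline_delta):
    """Full default simulation grid (12 coverages x 6 efficiencies x 10 repeats)."""
    return bl.build_null_grid(seed=master_seed, delta_px=pipeline_delta)


@pytest.fixture(scope="session")
def null_baseline(null_grid):
    return bl.fit_baseline(null_grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(MASTER_SEED)
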