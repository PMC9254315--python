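"""Shared fixtures: a small phantom, the desk-scale acquisition layout and
a simulated dataset reused by the expensive integration tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from hypica import synthetic as syn
from hypica.containers import RunSpec

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")

SCALED_RUNS = (150, 300, 300, 300)
SCALED_BLOCK_VOLUMES = 100
SCALED_SAMPLES_PER_BLOCK = 4


@pytest.fixture(scope="session")
def run_spec_small() -> RunSpec:
    return RunSpec(SCALED_RUNS, 1.18, (-30.0, 0.0, 30.0, 80.0))


@pytest.fixture(scope="session")
def phantom():
    return syn.make_phantom_anatomy((24, 24, 24), seed=7)


@pytest.fixture(scope="session")
def serum_small(run_spec_small):
    times = syn.default_serum_times(run_spec_small,
                                    block_multiple=SCALED_SAMPLES_PER_BLOCK)
    return syn.simulate_serum_curves(times)


@pytest.fixture(scope="session")
def dataset_small(run_spec_small):
    """Three-subject desk-scale dataset shared across integration tests."""
    return syn.simulate_dataset(
        n_subjects=3,
        grid_shape=(24, 24, 24),
        run_spec=run_spec_small,
        block_volumes=SCALED_BLOCK_VOLUMES,
        samples_per_block=SCALED_SAMPLES_PER_BLOCK,
        seed=42,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
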