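"""Shared fixtures: a standard synthetic cohort and its derived artifacts.

The expensive objects (default cohort, processed tracks, observation cloud,
net-probability maps) are session-scoped and shared by the recovery,
model-selection and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from cmacdyn.crosscorr import extract_all
from cmacdyn.preprocess import filter_tracks, process_table
from cmacdyn.probmaps import lag_ordering_map, sign_probability_map
from cmacdyn.synthetic import default_plastic_config, generate_cohort

COHORT_SEED = 1


@pytest.fixture(scope="session")
def cohort_config():
    return default_plastic_config(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_table(cohort_config):
    return generate_cohort(cohort_config)


@pytest.fixture(scope="session")
def processed_tracks(cohort_table):
    return filter_tracks(process_table(cohort_table))


@pytest.fixture(scope="session")
def observations(processed_tracks):
    return extract_all(processed_tracks)


@pytest.fixture(scope="session")
def area_map(observations):
    return sign_probability_map(observations, "area")


@pytest.fixture(scope="session")
def tension_map(observations):
    return sign_probability_map(observations, "tension")


@pytest.fixture(scope="session")
def lag_map(observations):
    return lag_ordering_map(observations)


@pytest.fixture(scope="session")
def small_cohort_table():
    """A fast, small cohort for I/O and pipeline smoke tests."""
    cfg = default_plastic_config(n_cells=3, tracks_per_cell=10, seed=5)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
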