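"""Shared fixtures: synthetic cohorts at two scales.

``small_cohort`` is a fast miniature for unit tests; ``default_cohort`` /
``default_balanced`` / ``default_idealized`` run the generator at the
study's full design (14 animals, 800/100/100 sequences) and are
session-scoped because several analyses reuse them.
"""

from __future__ import annotations

import numpy as np
import pytest

from oddnet import preprocessing as pp
from oddnet.synthetic_data import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(
        n_animals=3, n_standards=40, n_d1=5, n_d2=5, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_balanced(small_cohort):
    return pp.balance_cohort(pp.preprocess(small_cohort))


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_balanced(default_cohort):
    return pp.balance_cohort(pp.preprocess(default_cohort))


@pytest.fixture(scope="session")
def default_idealized(default_balanced):
    return pp.build_idealized_dataset(default_balanced)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
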