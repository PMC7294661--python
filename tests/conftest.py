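import numpy as np
import pytest

from cipdus import (
    cohort_to_frame,
    generate_cohort,
    published_cohort_config,
    scale_config,
)


@pytest.fixture(scope="session")
def published_config():
    return published_cohort_config(seed=0)


@pytest.fixture(scope="session")
def small_cohort(published_config):
    """One cohort at the derivation-study size (22 events / 54 non-events)."""
    return generate_cohort(published_config)


@pytest.fixture(scope="session")
def small_frame(small_cohort):
    return cohort_to_frame(small_cohort)


@pytest.fixture(scope="session")
def big_cohort(published_config):
    """Cohort at x100 scale (2200 events / 5400 non-events) for stochastic checks."""
    return generate_cohort(scale_config(published_config, 100))


@pytest.fixture(scope="session")
def big_frame(big_cohort):
    return cohort_to_frame(big_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)
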