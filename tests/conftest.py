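import numpy as np
import pytest

from bleedrisk.synthetic import (SyntheticCohortConfig, generate_cohort,
                                 generate_worked_fixtures)


@pytest.fixture(scope="session")
def fixtures():
    return generate_worked_fixtures()


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-patient synthetic cohort, shared across tests for speed."""
    return generate_cohort(SyntheticCohortConfig(n_patients=120, seed=42))


@pytest.fixture(scope="session")
def default_cohort():
    """A full-size default-config cohort (seed 1)."""
    return generate_cohort(SyntheticCohortConfig(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
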