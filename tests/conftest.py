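import numpy as np
import pytest
from hypothesis import settings

from milkdx import CohortConfig, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """Study-scale synthetic cohort at a pinned seed (150 subjects)."""
    return generate_cohort(CohortConfig(n=150, seed=7))


@pytest.fixture(scope="session")
def large_cohort():
    """Large cohort for calibration-recovery checks."""
    return generate_cohort(CohortConfig(n=10000, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_separable():
    """Six subjects with one overlapping tie at the Youden boundary."""
    values = [5, 6, 7, 1, 2, 6]
    outcomes = ["allergic"] * 3 + ["tolerant"] * 3
    return values, outcomes
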