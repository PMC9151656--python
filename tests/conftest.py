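import pytest

from svtopo.synthetic_data import SimParams, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """30-sample seeded cohort shared by read-only tests."""
    return simulate_cohort(SimParams(seed=7, n_samples=30))


@pytest.fixture(scope="session")
def full_cohort():
    """The 200-sample default-condition cohort (seed 7)."""
    return simulate_cohort(SimParams(seed=7, n_samples=200))
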