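import numpy as np
import pytest

from ttakit.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Standard two-arm simulated cohort with the default planted arm effect."""
    return simulate_cohort(SimConfig(n_per_arm=30, seed=11))


@pytest.fixture(scope="session")
def zero_cohort():
    """Cohort with no decline, drift or noise: every indicator constant."""
    return simulate_cohort(SimConfig.zero_dynamics(n_per_arm=10, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
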