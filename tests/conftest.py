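import numpy as np
import pytest

from phbreak import SimParams, make_toy_reference, simulate_cohort


@pytest.fixture(scope="session")
def toy_ref():
    return make_toy_reference(seed=1)


@pytest.fixture(scope="session")
def sim_small(toy_ref):
    """A 300-patient simulated cohort shared across read-only tests."""
    return simulate_cohort(SimParams(n_patients=300, seed=7), toy_ref)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
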