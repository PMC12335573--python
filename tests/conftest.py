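import numpy as np
import pytest

from cardalign import design, participants, pipeline


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def cfg():
    return design.DesignConfig()


@pytest.fixture(scope="session")
def small_cohorts():
    """One small simulated study (40 participants/group) shared across tests."""
    return pipeline.simulate_study(seed=99, n_per_group=40, n_calibration=120)


@pytest.fixture(scope="session")
def unbiased_records(small_cohorts):
    return small_cohorts["records"]["unbiased"]


@pytest.fixture(scope="session")
def behavior():
    return participants.BehaviorParams()
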