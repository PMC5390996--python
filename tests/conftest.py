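import hypothesis
import numpy as np
import pytest

from mrmselect import make_scenario

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def spurious_spec():
    """Small spurious-scenario condition for unit tests."""
    return make_scenario("spurious", n=30, n_reps=50, master_seed=123)


@pytest.fixture(scope="session")
def tapering_spec():
    return make_scenario("tapering", n=30, n_reps=50, master_seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)
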