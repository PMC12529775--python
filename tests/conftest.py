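import numpy as np
import pytest
from hypothesis import settings

from predkin.synthetic import make_catalysis_study

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study():
    """One synthetic free-vs-encapsulated study shared across tests."""
    return make_catalysis_study(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
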