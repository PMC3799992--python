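import numpy as np
import pytest
from hypothesis import settings

from lpmc import energetics
from lpmc.io_cli import packaged_sequence

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model_f0():
    return energetics.default_model(0.0)


@pytest.fixture(scope="session")
def model_f5():
    return energetics.default_model(5.0)


@pytest.fixture(scope="session")
def h31_sequence():
    return packaged_sequence()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
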