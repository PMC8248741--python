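import numpy as np
import pytest

from p2ca.params import ModelParameters
from p2ca.simulation import equilibrate


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def resting(params):
    """Equilibrated resting state of the intact cell (naive P2X7 pool)."""
    return equilibrate(params)


@pytest.fixture(scope="session")
def resting_sensitized(params):
    return equilibrate(params, initial_markov="sensitized_C4")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
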