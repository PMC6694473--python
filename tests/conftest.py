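import numpy as np
import pytest

from pahcea import default_parameters
from pahcea.states import FunctionalClass


@pytest.fixture(scope="session")
def params():
    """The bundled canonical parameterization (treat as read-only)."""
    return default_parameters()


@pytest.fixture()
def params_copy(params):
    """A mutable deep copy for tests that tweak inputs."""
    return params.model_copy(deep=True)


@pytest.fixture(scope="session")
def fc2():
    return FunctionalClass.FC2


@pytest.fixture(scope="session")
def fc3():
    return FunctionalClass.FC3


@pytest.fixture()
def rng():
    return np.random.default_rng(20250925)
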