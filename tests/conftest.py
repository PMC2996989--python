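import numpy as np
import pytest

from episens.simulate import E1, E2, generate_library, scenario_spec


@pytest.fixture(scope="session")
def null_library():
    """A generated no-interaction library shared by read-only tests."""
    return generate_library(scenario_spec("null", seed=101))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def env_pair():
    return E1, E2
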