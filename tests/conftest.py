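import numpy as np
import pytest

from sisifus.phantom import make_fixture


@pytest.fixture(scope="session")
def flat_bundle():
    return make_fixture("flat", seed=11)


@pytest.fixture(scope="session")
def lp_exact_bundle():
    return make_fixture("lp_exact", seed=7)


@pytest.fixture(scope="session")
def step_bundle():
    return make_fixture("step_edge", seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
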