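import numpy as np
import pytest

from shapelearn import ChannelBasis, generate_design, make_shape_space


@pytest.fixture(scope="session")
def basis():
    return ChannelBasis()


@pytest.fixture(scope="session")
def shape_space():
    return make_shape_space()


@pytest.fixture(scope="session")
def exp1_design():
    return generate_design(1, seed=101)


@pytest.fixture(scope="session")
def exp2_design():
    return generate_design(2, seed=202)


@pytest.fixture(scope="session")
def shape_only_design():
    return generate_design("shape_only", seed=303)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
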