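import numpy as np
import pytest

from gqfold.registry import REGISTRY, get_params


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def params_333():
    return get_params("333")


@pytest.fixture
def params_233():
    return get_params("233")


@pytest.fixture
def registry():
    return REGISTRY
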