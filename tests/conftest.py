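import numpy as np
import pytest

from spcmix import make_distribution


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def std_normal():
    return make_distribution("normal", (0.0, 1.0), 0.0)


@pytest.fixture
def exp1():
    return make_distribution("exponential", (1.0,), 0.0)
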