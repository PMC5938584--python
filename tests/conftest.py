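import numpy as np
import pytest

from iriscale import default_grid, h_sara_stack


@pytest.fixture
def grid():
    return default_grid()


@pytest.fixture
def sara_stack():
    """The measured iridescent ridge multilayer: 119 nm air / 85 nm chitin x2."""
    return h_sara_stack()


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
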