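import numpy as np
import pytest

from helpers import make_hset


@pytest.fixture
def two_snp_set():
    """The 2-instrument hand example: weights (1, 4), ratios (0.5, 0.3)."""
    return make_hset(bx=[0.1, 0.2], sx=[0.02, 0.02],
                     by=[0.05, 0.06], sy=[0.1, 0.1])


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_915)
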