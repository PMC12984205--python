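import numpy as np
import pytest

from sbmn.module import make_module_params
from sbmn.autodiff import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_setup(rng):
    """Tiny module instance (B=2, M=3, H=8) for oracle comparisons."""
    H, B, M = 8, 2, 3
    params = make_module_params(rng, H)
    x = Tensor(rng.standard_normal((B, H)))
    m = Tensor(rng.standard_normal((M, H)))
    return x, m, params
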