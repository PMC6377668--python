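import numpy as np
import pytest

from heidercoop.core_model import init_reputation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_reputation(n, rng, sparsity=0.0):
    """Random valid reputation matrix (off-diagonal uniform in [-1, 1])."""
    S = rng.uniform(-1.0, 1.0, size=(n, n))
    if sparsity:
        S[rng.random((n, n)) < sparsity] = 0.0
    np.fill_diagonal(S, 1.0)
    return S


@pytest.fixture
def small_matrix(rng):
    return random_reputation(5, rng)
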