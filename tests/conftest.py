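import numpy as np
import pytest

from gradeca import to_probability_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def diag2():
    """2x2 diagonal probability matrix: rho* = 0.75, tau = 0.5."""
    return to_probability_matrix(np.array([[1.0, 0.0], [0.0, 1.0]]))


@pytest.fixture
def diag3():
    """Uniform 3x3 diagonal: rho* = 8/9, tau = 2/3."""
    return to_probability_matrix(np.eye(3))


@pytest.fixture
def independent3():
    """Outer-product (independent) 3x3 matrix: h == 1, rho* = tau = 0."""
    return to_probability_matrix(np.outer([0.2, 0.3, 0.5], [0.1, 0.4, 0.5]))
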