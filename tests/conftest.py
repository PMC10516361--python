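import numpy as np
import pytest

from resconn.features import CorrelationMatrix


def random_matrix(rng: np.random.Generator, L: int) -> CorrelationMatrix:
    """Dense symmetric matrix with uniform(0, 1) entries for every pair."""
    m = CorrelationMatrix(L)
    for i in range(1, L + 1):
        for j in range(i + 1, L + 1):
            m.set(i, j, float(rng.random()))
    return m


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix():
    """L=4 matrix used in hand-worked cumuCC checks."""
    return CorrelationMatrix(4, {
        (1, 2): 4.0, (1, 3): 3.0, (2, 3): 2.0,
        (1, 4): 0.5, (2, 4): 0.5, (3, 4): 0.5,
    })
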