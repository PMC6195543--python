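import numpy as np
import pytest

from mutclust.bde_scoring import ScoringConfig
from mutclust.data_io import MutationMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def plain_config():
    """BDe score with all penalties off."""
    return ScoringConfig(chi=1.0, prior_penalty=1.0, global_penalty=1.0)


@pytest.fixture
def small_matrix():
    D = np.array(
        [
            [1, 0, 1],
            [0, 1, 1],
            [1, 1, 0],
            [0, 0, 0],
        ]
    )
    return MutationMatrix(["s1", "s2", "s3", "s4"], ["TP53", "KRAS", "BRAF"], D)


@pytest.fixture
def data4(rng):
    """N=200 binary data over 4 weakly dependent columns."""
    N = 200
    a = (rng.random(N) < 0.4).astype(int)
    b = (rng.random(N) < np.where(a == 1, 0.7, 0.2)).astype(int)
    c = (rng.random(N) < 0.3).astype(int)
    d = (rng.random(N) < np.where(b + c >= 1, 0.6, 0.15)).astype(int)
    return np.column_stack([a, b, c, d])
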