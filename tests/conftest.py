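import numpy as np
import pytest

from renyite.kernels import GramMatrix, median_bandwidth, rbf_gram


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_gram(rng, n=20, d=3) -> GramMatrix:
    """A generic trace-normalized RBF Gram matrix from Gaussian points."""
    pts = rng.normal(size=(n, d))
    return rbf_gram(pts, median_bandwidth(pts))


@pytest.fixture
def gram_factory(rng):
    def make(n=20, d=3):
        return random_gram(rng, n, d)

    return make
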