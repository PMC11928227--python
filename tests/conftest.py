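import numpy as np
import pytest

from fedsim import make_blobs


@pytest.fixture
def binary_blobs():
    """Separable two-class blobs, 200 x 5."""
    return make_blobs(n=200, d=5, C=2, separation=5.0, seed=0)


@pytest.fixture
def multiclass_blobs():
    """Four-class blobs, 240 x 8."""
    return make_blobs(n=240, d=8, C=4, separation=6.0, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
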