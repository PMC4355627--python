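import numpy as np
import pytest

from voxtex import QuantizedVolume


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_qvol(rng):
    """A 5x5x5 quantized volume with 4 gray levels."""
    return QuantizedVolume(rng.integers(1, 5, size=(5, 5, 5)), Ng=4, Qg=4)


def random_symmetric_p(rng, ng):
    """A random symmetric probability matrix (valid normalized GLCM)."""
    a = rng.random((ng, ng))
    a = a + a.T
    return a / a.sum()
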