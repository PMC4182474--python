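import numpy as np
import pytest

from dcequant import SequenceSpec, default_aif
from dcequant.phantom import make_phantom_truth


@pytest.fixture(scope="session")
def seq():
    """The protocol's acquisition grid (206 frames @ 4.8 s, 7 TRs, 4 b)."""
    return SequenceSpec()


@pytest.fixture(scope="session")
def aif(seq):
    return default_aif(seq)


@pytest.fixture
def small_truth():
    """6x6x2 phantom with a 2-voxel-radius tumour, noise-free."""
    return make_phantom_truth(shape=(6, 6, 2), tumour_radius=2.0, seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
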