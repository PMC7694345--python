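import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from sparsefuse import CSCConfig, PhantomSpec, make_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_pair_64():
    return make_pair(PhantomSpec(size=64, seed=7))


@pytest.fixture(scope="session")
def phantom_pair_128():
    return make_pair(PhantomSpec(size=128, seed=7))


@pytest.fixture
def fast_csc():
    """Reduced-size dictionary and iteration caps for small unit tests."""
    return CSCConfig(max_inner=50, max_outer=5, n_cartoon=4, n_texture=8, taper=0)
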