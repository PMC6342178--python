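import numpy as np
import pytest

from habsuit.synthetic import make_gradient_system


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def gradient_small():
    """Small gradient study system shared by read-only tests."""
    return make_gradient_system(size=120, n_candidates=5000, seed=11)
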