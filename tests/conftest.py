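import numpy as np
import pytest

from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def float64_engine():
    """Run the autograd core in float64 for finite-difference checks."""
    import anorak.nn.tensor as T

    old = T.DTYPE
    T.DTYPE = np.float64
    yield
    T.DTYPE = old
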