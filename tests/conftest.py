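import numpy as np
import pytest

from echoguide import make_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One default 8-organ phantom shared across the suite (expensive to build)."""
    return make_phantom(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
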