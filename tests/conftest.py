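import numpy as np
import pytest

from mrnatrack import AnteriorAxis


@pytest.fixture
def axis():
    """Anterior at the origin, posterior towards +x."""
    return AnteriorAxis(origin=(0.0, 0.0), posterior_unit=(1.0, 0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
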