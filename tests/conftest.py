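import numpy as np
import pytest

from reflectim.beads import BeadsConfig


@pytest.fixture
def config():
    """Default task: q = 0.8, 20-bead cap, unit reward, symmetric prior."""
    return BeadsConfig()


@pytest.fixture
def small_config():
    """A 4-bead horizon small enough for exhaustive enumeration."""
    return BeadsConfig(d_max=4)


@pytest.fixture
def rng():
    return np.random.default_rng(20151102)
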