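import numpy as np
import pytest

import surbop as sb


@pytest.fixture(scope="session")
def band():
    return sb.BandSpec.default_aliphatic()


@pytest.fixture(scope="session")
def limits():
    return sb.ControlLimits(15_000.0)


@pytest.fixture
def random_pulse(limits):
    """A reproducible 24-step random shape at the flagship timestep."""
    return sb.random_start(24, 0.5e-6, limits, seed=5)
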