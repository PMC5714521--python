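import numpy as np
import pytest

from wbreg.phantom import generate_anatomy, warp_case


@pytest.fixture(scope="session")
def anatomy():
    """Session-wide 64^3 phantom anatomy (seed 7)."""
    return generate_anatomy(7)


@pytest.fixture(scope="session")
def phantom_case(anatomy):
    """Session-wide warped phantom case with default magnitudes."""
    return warp_case(anatomy, 7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
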