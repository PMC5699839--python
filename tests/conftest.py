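import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from capdec.filters import design_bessel4

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def bessel10():
    """The reference output-filter emulation: 10 kHz 4-pole Bessel at 100 kHz."""
    return design_bessel4(10e3, 100e3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
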