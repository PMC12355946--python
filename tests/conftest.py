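import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: headspace/solution ratios of the 20 mL vial design (fills 1..18 mL)
DESIGN_RATIOS = tuple((20.0 - f) / f for f in (1.0, 2.0, 5.0, 10.0, 15.0, 18.0))


@pytest.fixture(scope="session")
def design_ratios():
    return DESIGN_RATIOS


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
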