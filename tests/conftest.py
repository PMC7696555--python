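import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from colorkym import build_continuous_scale, default_ph_chart

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ph_chart():
    return default_ph_chart()


@pytest.fixture(scope="session")
def ph_scale(ph_chart):
    return build_continuous_scale(ph_chart, 0.1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20201110)
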