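import pytest
from hypothesis import HealthCheck, settings

from dfdscan.synthetic_data import make_demo_fixture

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo():
    return make_demo_fixture()


@pytest.fixture(scope="session")
def demo_config(demo):
    from dfdscan.dfd import DFDConfig

    return DFDConfig(required_phyla=demo.phyla)
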