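import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def il18_instruments():
    from ivmr.datasets import load_il18_instruments

    return load_il18_instruments()


@pytest.fixture(scope="session")
def ibd_outcomes():
    from ivmr.datasets import load_ibd_outcomes

    return load_ibd_outcomes()
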