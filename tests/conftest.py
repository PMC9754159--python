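import pytest
from hypothesis import HealthCheck, settings

import pphcea as P

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config() -> P.ModelConfig:
    return P.load_config()


@pytest.fixture(scope="session")
def params(config) -> P.ParameterSet:
    return config.params


@pytest.fixture(scope="session")
def life_table() -> P.LifeTable:
    return P.load_default_life_table()
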