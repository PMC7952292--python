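import pytest
from hypothesis import HealthCheck, settings

from eq5dval import GeneratorConfig, generate_population, toy_value_set

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def vs5():
    return toy_value_set("5L")


@pytest.fixture(scope="session")
def vs3():
    return toy_value_set("3L")


@pytest.fixture(scope="session")
def small_survey():
    """A 300-record synthetic survey used by I/O and report tests."""
    return generate_population(GeneratorConfig(n=300, seed=7))


@pytest.fixture(scope="session")
def medium_survey():
    """A 4000-record synthetic survey at the emulated study's scale."""
    return generate_population(GeneratorConfig(n=4000, seed=11))
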