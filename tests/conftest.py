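import hypothesis
import pytest

from strobescreen.synthetic_data import (
    SimConfig,
    default_phenotypes,
    gen_battery_schedule,
)

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def schedule():
    """Full ~20 min battery (acoustic, tap, light, blue/green strobes)."""
    return gen_battery_schedule(SimConfig())


@pytest.fixture(scope="session")
def mini_schedule():
    """Reduced battery: the two strobe segments plus rest."""
    return gen_battery_schedule(SimConfig(full_battery=False))


@pytest.fixture(scope="session")
def phenos():
    return default_phenotypes()
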