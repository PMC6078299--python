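import numpy as np
import pytest

from sleepdyn import (
    EnvironmentSpec,
    HarmonicRate,
    SleepStrategy,
    SyntheticSpec,
    random_initial_density,
)


@pytest.fixture(scope="session")
def bump_n0():
    """Seeded smooth initial density for the default solver domain."""
    return random_initial_density(SyntheticSpec(seed=1), d=6.0, m=8.0)


@pytest.fixture()
def constant_env():
    """Constant-rate environment: B=5, Gamma=2.5, alpha=2."""
    return EnvironmentSpec(
        birth=HarmonicRate(5.0),
        mortality=HarmonicRate(2.5),
        foraging=HarmonicRate(2.0),
        birth_coupled_to_activity=True,
    )


@pytest.fixture()
def waking():
    return SleepStrategy(rel_amp=0.0)


@pytest.fixture()
def full_sleep():
    return SleepStrategy(rel_amp=1.0, phase=0.0)
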