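import numpy as np
import pytest
from hypothesis import settings

from odp import ScaleGrid, Signal, SynthConfig, harmonic

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def sine_1hz() -> Signal:
    """The noiseless 1 Hz reference signal: 10 s at 400 Hz."""
    return harmonic(SynthConfig(component_freqs=(1.0,), component_amps=(1.0,)))


@pytest.fixture(scope="session")
def composite_1hz_2hz() -> Signal:
    """The 1 Hz + 2 Hz composite imitating a dicrotic pulse."""
    return harmonic(
        SynthConfig(component_freqs=(1.0, 2.0), component_amps=(1.0, 0.5))
    )


@pytest.fixture(scope="session")
def small_grid() -> ScaleGrid:
    """A cheap feature-band grid for unit tests."""
    return ScaleGrid(min_scale=200, max_scale=1000, count=12)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
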