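import numpy as np
import pytest

from duokit import UniformSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def make_sinusoid(
    period: float,
    duration: float = 168.0,
    dt: float = 0.1,
    amplitude: float = 1.0,
    mesor: float = 5.0,
    phase: float = 0.0,
    kind: str = "temperature",
) -> UniformSeries:
    """Gap-free sinusoidal series (temperature kind so negatives are allowed)."""
    t = np.arange(int(round(duration / dt))) * dt
    y = mesor + amplitude * np.cos(2 * np.pi * t / period - phase)
    return UniformSeries(t0=0.0, dt=dt, values=y, kind=kind)


@pytest.fixture
def sinusoid_4hr():
    return make_sinusoid(4.0)
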