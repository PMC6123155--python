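import numpy as np
import pytest

from respsurro import BreathingModelParams, RespTrace, SurrogateDistortion


def make_sinusoid(
    period: float = 4.0,
    duration: float = 20.0,
    rate: float = 25.0,
    amplitude: float = 50.0,
    offset: float = 50.0,
    phase: float = 0.0,
) -> RespTrace:
    """offset + amplitude*sin(2*pi*t/period + phase) on a uniform grid."""
    t = np.arange(int(round(duration * rate))) / rate
    a = offset + amplitude * np.sin(2 * np.pi * t / period + phase)
    return RespTrace(timestamps=t, amplitudes=a, beam_on=np.zeros(t.size, bool))


def make_raised_cosine(
    period: float = 4.0,
    duration: float = 20.0,
    rate: float = 25.0,
    depth: float = 100.0,
) -> RespTrace:
    """depth*(1-cos(2*pi*t/period))/2: EOE at t=0, EOI at t=period/2."""
    t = np.arange(int(round(duration * rate))) / rate
    a = depth * (1.0 - np.cos(2 * np.pi * t / period)) / 2.0
    return RespTrace(timestamps=t, amplitudes=a, beam_on=np.zeros(t.size, bool))


@pytest.fixture
def sinusoid():
    return make_sinusoid()


@pytest.fixture
def default_params():
    return BreathingModelParams(mean_period=4.0, duration=40.0, seed=0)


@pytest.fixture
def identity():
    return SurrogateDistortion()
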