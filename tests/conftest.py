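import numpy as np
import pytest

from murmurkit.io import VALVES, AudioSignal
from murmurkit.sync import ValveChannelSet

RATE = 4000


def impulse_train(duration, rate=RATE, period=1.0, start=0.5, freq=60.0, width=0.05):
    """Damped-sinusoid transients at known onsets: a minimal heartbeat fixture."""
    n = int(duration * rate)
    x = np.zeros(n)
    w = int(width * rate)
    t = np.arange(w) / rate
    burst = np.exp(-t / 0.01) * np.sin(2 * np.pi * freq * t)
    onset = start
    while onset < duration - width:
        i = int(round(onset * rate))
        x[i : i + w] += burst
        onset += period
    return AudioSignal(x, rate)


def sine(freq, duration=2.0, rate=RATE, amp=0.5):
    t = np.arange(int(duration * rate)) / rate
    return AudioSignal(amp * np.sin(2 * np.pi * freq * t), rate)


@pytest.fixture
def beat_signal():
    return impulse_train(duration=10.5, period=1.0, start=0.5)


@pytest.fixture
def four_identical_sines():
    sig = sine(100.0, duration=3.0)
    channels = {v: AudioSignal(sig.samples.copy(), sig.rate) for v in VALVES}
    return ValveChannelSet(channels=channels, label="absent", patient_id="t0", lineage="t0")


@pytest.fixture
def beat_group():
    base = impulse_train(duration=6.0, period=0.8, start=0.4)
    channels = {v: AudioSignal(base.samples.copy(), base.rate) for v in VALVES}
    return ValveChannelSet(channels=channels, label="present", patient_id="t1", lineage="t1")
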