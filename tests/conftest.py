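import numpy as np
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("det", derandomize=True, deadline=None)
hyp_settings.load_profile("det")

from pouremg.granular_labels import Direction, GestureLabel
from pouremg.signal_io import RecordingSession, SignalWindow
from pouremg.synthetic_emg import SynthParams, make_protocol, synthesize_session


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """One repetition of the full protocol, synthesized with a fixed seed."""
    plan = make_protocol(1, seed=7)
    return synthesize_session(plan, SynthParams(seed=7))


@pytest.fixture
def toy_window(rng):
    return SignalWindow(rng.standard_normal((4, 481)), GestureLabel(Direction.HOLD), 0.0)


def make_sine_session(freq_hz, fs=1000.0, duration_s=2.0, n_channels=4):
    t = np.arange(int(fs * duration_s)) / fs
    sig = np.tile(np.sin(2 * np.pi * freq_hz * t), (n_channels, 1))
    return RecordingSession(sig, fs, [])
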