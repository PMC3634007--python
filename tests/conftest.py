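import numpy as np
import pytest

from gravsep.recording import TriaxialRecording


@pytest.fixture
def rng():
    return np.random.default_rng(20130423)


@pytest.fixture
def make_recording():
    """Factory: recording from an (n, 3) array (default fs 80 Hz)."""

    def _make(data, fs=80.0, start_time=0.0):
        return TriaxialRecording(fs=fs, data=np.asarray(data, dtype=float), start_time=start_time)

    return _make


@pytest.fixture
def static_recording(make_recording):
    """Factory: constant-orientation noiseless recording of given length."""

    def _make(vector=(0.0, 0.0, 1.0), duration_s=60.0, fs=80.0):
        n = int(round(duration_s * fs))
        return make_recording(np.tile(np.asarray(vector, dtype=float), (n, 1)), fs=fs)

    return _make


@pytest.fixture
def sinusoid_recording(make_recording):
    """Factory: one-axis sinusoid (amplitude in g) on top of a base vector."""

    def _make(freq_hz, amplitude_g=1.0, axis=0, base=(0.0, 0.0, 0.0), duration_s=120.0, fs=80.0):
        n = int(round(duration_s * fs))
        t = np.arange(n) / fs
        data = np.tile(np.asarray(base, dtype=float), (n, 1))
        data[:, axis] += amplitude_g * np.sin(2 * np.pi * freq_hz * t)
        return make_recording(data, fs=fs)

    return _make
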