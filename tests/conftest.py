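import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from thetanet.preprocess import Event, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(data, fs=250.0, events=None):
    """Recording with generic channel labels for ad-hoc arrays."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return Recording(
        data=data,
        sample_rate=fs,
        channel_labels=[f"ch{i}" for i in range(data.shape[0])],
        events=events or [],
    )


def sine_recording(freqs_hz, fs=250.0, duration=20.0, amplitude=1.0, noise_sd=0.0,
                   seed=0):
    """One channel per frequency; optional white noise."""
    t = np.arange(int(duration * fs)) / fs
    rng = np.random.default_rng(seed)
    rows = [
        amplitude * np.sin(2 * np.pi * f * t) + noise_sd * rng.standard_normal(t.size)
        for f in np.atleast_1d(freqs_hz)
    ]
    return make_recording(np.array(rows), fs=fs)
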