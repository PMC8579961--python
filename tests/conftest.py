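import numpy as np
import pytest

from phaselink import BandSpec, EpochedRecording

THETA = BandSpec("theta", 4.0, 7.0)
BETA = BandSpec("beta", 13.0, 30.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(data, fs=250.0, labels=None, epoch_length_s=None):
    data = np.asarray(data, dtype=float)
    if labels is None:
        labels = [f"CH{i + 1}" for i in range(data.shape[0])]
    if epoch_length_s is None:
        epoch_length_s = data.shape[2] / fs
    return EpochedRecording(data, fs, labels, epoch_length_s)


def lagged_pair_recording(
    rng, f_hz=5.5, lag=np.pi / 2, n_epochs=75, fs=250.0, epoch_s=4.0, noise=0.0
):
    """Two channels driven by one random-phase tone, second lagged; optional noise."""
    n = int(fs * epoch_s)
    t = np.arange(n) / fs
    phases = rng.uniform(0, 2 * np.pi, n_epochs)
    x = np.cos(2 * np.pi * f_hz * t[None, :] + phases[:, None])
    y = np.cos(2 * np.pi * f_hz * t[None, :] + phases[:, None] - lag)
    data = np.stack([x, y])  # (2, epochs, samples)
    if noise:
        data = data + noise * rng.standard_normal(data.shape)
    return make_recording(data, fs=fs)
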