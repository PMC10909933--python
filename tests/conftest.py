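import numpy as np
import pytest

from metastab.containers import ContinuousEEG, EpochedEEG


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_continuous(rng):
    """10 s, 4-channel, 1 kHz record with three pulse markers."""
    fs = 1000.0
    t = np.arange(int(10 * fs)) / fs
    data = np.stack([
        10 * np.sin(2 * np.pi * 10 * t + k) + rng.normal(0, 1, t.size)
        for k in range(4)
    ])
    return ContinuousEEG(
        data=data, fs=fs,
        channel_names=["C3", "C4", "Cz", "Pz"],
        events=np.array([2000, 4000, 6000]),
    )


@pytest.fixture
def tiny_epochs(rng):
    """8 epochs x 6 channels x 800 samples of structured noise."""
    data = rng.normal(0, 5, (8, 6, 800))
    return EpochedEEG(
        data=data, fs=1000.0,
        channel_names=[f"ch{i}" for i in range(6)],
        pulse_sample=300,
    )
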