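import numpy as np
import pytest

from earseiz.montage import ALL_ELECTRODES, MultichannelSignal, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """2-second, 250 Hz referential recording over the full electrode set."""
    fs = 250.0
    data = rng.normal(0.0, 20.0, (len(ALL_ELECTRODES), int(2 * fs)))
    return Recording(fs, list(ALL_ELECTRODES), data)


def make_signal(data, fs=250.0, names=None):
    data = np.asarray(data, dtype=float)
    if names is None:
        names = [f"ch{i}" for i in range(data.shape[0])]
    return MultichannelSignal(fs, list(names), data)
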