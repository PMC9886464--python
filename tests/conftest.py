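import numpy as np
import pytest

from pcgkit.io import Signal
from pcgkit.synth import synth_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def sine_100hz():
    """1 s of a unit 100 Hz sine at 8000 Hz (integer number of cycles)."""
    t = np.arange(8000) / 8000.0
    return Signal(np.sin(2 * np.pi * 100 * t), 8000.0)


@pytest.fixture(scope="session")
def small_dataset():
    """6 recordings per class, 3 s at 8000 Hz — shared read-only fixture."""
    signals, manifest = synth_dataset(6, duration=3.0, rate=8000.0, seed=42)
    return signals, manifest
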