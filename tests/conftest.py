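import numpy as np
import pytest

from pmconn.containers import Channel, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_recording(rng):
    """Two independent white-noise channels, 20 s at 1 kHz."""
    return Recording(
        signal=rng.standard_normal((2, 20000)),
        fs_hz=1000.0,
        channels=[Channel("ch0", "RFA", "L5"), Channel("ch1", "CFA", "L2/3")],
    )


def sinusoid(f_hz: float, fs_hz: float, duration_s: float, amplitude: float = 1.0) -> np.ndarray:
    t = np.arange(int(duration_s * fs_hz)) / fs_hz
    return amplitude * np.sin(2 * np.pi * f_hz * t)
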