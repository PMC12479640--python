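import numpy as np
import pytest

from swallowsound.audio_io import AudioSignal


@pytest.fixture
def fs() -> int:
    return 44_100


def make_tone(freq_hz: float, duration_s: float, amplitude: float,
              fs: int = 44_100, phase: float = 0.0) -> AudioSignal:
    """Quantized pure sine, used as an analytically known segment."""
    t = np.arange(int(round(duration_s * fs))) / fs
    x = np.rint(amplitude * np.sin(2 * np.pi * freq_hz * t + phase))
    return AudioSignal(x.astype(np.int16), fs, 16)


@pytest.fixture
def tone_segment(fs) -> AudioSignal:
    return make_tone(2000.0, 0.5, 20_000, fs)
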