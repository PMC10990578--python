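import numpy as np
import pytest

from audioscene.audio_io import Waveform

SR = 16000


def make_tone(freq: float, duration: float = 1.0, amp: float = 1.0,
              sr: int = SR, phase: float = 0.0) -> Waveform:
    t = np.arange(int(duration * sr)) / sr
    return Waveform(amp * np.sin(2 * np.pi * freq * t + phase), sr, "tone")


@pytest.fixture
def tone():
    return make_tone


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
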