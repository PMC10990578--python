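"""Audio input/output and stimulus conditioning.

All downstream acoustic measures operate on :class:`Waveform`, a thin
container around a mono float array in nominal [-1, 1] full scale.
Conditioning follows the stimulus conventions used throughout the
package: scenes are RMS-matched and gated with short linear onset/offset
ramps so that clip boundaries do not inject spectral splatter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly


class AudioFormatError(ValueError):
    """Raised when a file cannot be read as PCM/float WAV audio."""


class DegenerateInputError(ValueError):
    """Raised when an operation is undefined for the given signal (e.g. all-zero)."""


@dataclass(frozen=True)
class Waveform:
    """Mono audio clip.

    Parameters
    ----------
    samples : np.ndarray
        Amplitude values, dimensionless, nominal range [-1, 1].
    sample_rate : int
        Sampling rate in Hz, > 0.
    scene_id : str
        Opaque identifier carried through the pipeline.
    """

    samples: np.ndarray
    sample_rate: int
    scene_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("Waveform requires a non-empty 1-D sample array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("Waveform samples must be finite")
        if int(self.sample_rate) <= 0:
            raise ValueError("sample_rate must be a positive integer")
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def duration(self) -> float:
        """Clip duration in seconds."""
        return self.samples.size / self.sample_rate

    def rms(self) -> float:
        """Root-mean-square amplitude over the whole clip."""
        return float(np.sqrt(np.mean(self.samples**2)))


_PCM_SCALE = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31,
              np.dtype("uint8"): None}


def read_wav(path: str | Path) -> Waveform:
    """Read a RIFF WAV file (16/32-bit PCM or float) as a mono Waveform.

    Multichannel input is averaged to mono; integer PCM is scaled to
    nominal [-1, 1] by the type's full-scale value.
    """
    path = Path(path)
    if not path.exists():
        raise AudioFormatError(f"no such audio file: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # scipy raises bare ValueError on bad chunks
        raise AudioFormatError(f"cannot read WAV file {path}: {exc}") from exc
    data = np.atleast_1d(data)
    if data.dtype == np.dtype("uint8"):
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype.kind == "i":
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype.kind == "f":
        samples = data.astype(np.float64)
    else:
        raise AudioFormatError(f"unsupported WAV sample format {data.dtype} in {path}")
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return Waveform(samples=samples, sample_rate=int(rate), scene_id=path.stem)


def write_wav(path: str | Path, w: Waveform, subtype: str = "float32") -> None:
    """Write a Waveform as WAV; ``subtype`` is ``float32`` or ``pcm16``."""
    path = Path(path)
    if subtype == "float32":
        wavfile.write(str(path), w.sample_rate, w.samples.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(w.samples, -1.0, 1.0 - 1.0 / 2**15)
        wavfile.write(str(path), w.sample_rate,
                      np.round(clipped * 2**15).astype(np.int16))
    else:
        raise ValueError(f"unknown WAV subtype {subtype!r}")


def normalize_rms(w: Waveform, target_rms: float = 0.05) -> Waveform:
    """Scale the clip to an exact target RMS amplitude."""
    if target_rms <= 0:
        raise ValueError("target_rms must be positive")
    current = w.rms()
    if current == 0.0:
        raise DegenerateInputError("cannot RMS-normalize an all-zero waveform")
    return replace(w, samples=w.samples * (target_rms / current))


def apply_ramps(w: Waveform, ramp_ms: float = 10.0) -> Waveform:
    """Impose linear onset/offset ramps on the first and last ``ramp_ms``."""
    n_ramp = int(round(w.sample_rate * ramp_ms / 1000.0))
    if w.samples.size <= 2 * n_ramp:
        raise ValueError(
            f"clip of {w.samples.size} samples too short for {ramp_ms} ms ramps")
    out = w.samples.copy()
    if n_ramp > 0:
        ramp = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
        out[:n_ramp] *= ramp
        out[-n_ramp:] *= ramp[::-1]
    return replace(w, samples=out)


def resample(w: Waveform, target_rate: int) -> Waveform:
    """Band-limited polyphase resampling to ``target_rate`` Hz."""
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == w.sample_rate:
        return w
    frac = Fraction(int(target_rate), int(w.sample_rate))
    out = resample_poly(w.samples, frac.numerator, frac.denominator)
    return Waveform(samples=out, sample_rate=int(target_rate), scene_id=w.scene_id)
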