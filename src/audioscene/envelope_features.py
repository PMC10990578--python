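"""Envelope-based intensity and rhythm measures.

The amplitude envelope drives the "rhythm" family of scene descriptors:
long-term and pause-corrected RMS (how much silence a scene contains),
the count of abrupt envelope peaks, burst detection (episodes rising at
least 4 dB above the preceding envelope minimum and lasting at least
20 ms), and the burst-duration ratio, a roughness index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, hilbert

from .audio_io import Waveform

_EPS = 1e-12


@dataclass(frozen=True)
class Envelope:
    """Non-negative amplitude envelope sampled at ``frame_rate`` Hz."""

    values: np.ndarray
    frame_rate: float
    source_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("Envelope requires a non-empty 1-D array")
        if np.any(values < 0):
            raise ValueError("Envelope values must be non-negative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def duration(self) -> float:
        return self.values.size / self.frame_rate


@dataclass(frozen=True)
class Burst:
    start: float
    end: float
    rise_db: float


@dataclass(frozen=True)
class BurstSet:
    """Detected envelope bursts, non-overlapping and time-ordered."""

    bursts: tuple[Burst, ...]
    total_duration: float

    def __post_init__(self) -> None:
        last_end = 0.0
        for b in self.bursts:
            if not (0.0 <= b.start < b.end <= self.total_duration + 1e-9):
                raise ValueError(f"burst {b} outside [0, {self.total_duration}]")
            if b.start < last_end - 1e-12:
                raise ValueError("bursts must be non-overlapping and ordered")
            last_end = b.end


def extract_envelope(w: Waveform, cutoff_hz: float = 30.0,
                     frame_rate: float = 1000.0,
                     edge_trim_ms: float = 20.0) -> Envelope:
    """Hilbert-magnitude envelope, smoothed and sampled at ``frame_rate``.

    Smoothing uses a zero-phase positive (Hann) kernel whose width
    matches a ~``cutoff_hz`` low-pass. A positive kernel has a monotone
    step response: unlike an IIR low-pass it cannot undershoot after an
    offset, which matters because a dB undershoot below the local
    envelope minimum would register as a spurious burst. The first and
    last ``edge_trim_ms`` are dropped to discard analytic-signal edge
    transients.
    """
    if cutoff_hz >= frame_rate / 2:
        raise ValueError("cutoff_hz must be below the Nyquist of frame_rate")
    # zero-pad before the FFT-based analytic transform: its circular
    # extension otherwise wraps edge ringing to the opposite end of the clip
    n = w.samples.size
    pad = 4096
    mag = np.abs(hilbert(np.concatenate([w.samples, np.zeros(pad)])))[:n]
    # Hann kernel of duration ~1/cutoff: -3 dB point near cutoff_hz
    klen = max(int(round(w.sample_rate / cutoff_hz)), 3)
    kernel = np.hanning(klen)
    kernel /= kernel.sum()
    smooth = fftconvolve(mag, kernel, mode="same")
    t_frames = np.arange(int(np.floor(w.duration * frame_rate))) / frame_rate
    t_samples = np.arange(mag.size) / w.sample_rate
    decim = np.interp(t_frames, t_samples, smooth)
    trim = int(round(edge_trim_ms * frame_rate / 1000.0))
    if decim.size > 2 * trim + 2:
        decim = decim[trim:decim.size - trim]
    return Envelope(values=np.maximum(decim, 0.0), frame_rate=frame_rate,
                    source_id=w.scene_id)


def longterm_rms(w: Waveform) -> float:
    """RMS over the whole clip."""
    return w.rms()


def pause_corrected_rms(w: Waveform, silence_floor_db: float = -60.0,
                        frame_ms: float = 10.0) -> tuple[float, float]:
    """RMS over non-silent frames plus the fraction of silent frames.

    Frames whose RMS falls more than ``silence_floor_db`` below the
    loudest frame are treated as pauses and excluded. Silence gating uses
    short-frame RMS rather than the analytic envelope: frame RMS is
    exactly zero in digital silence, whereas the Hilbert envelope leaks a
    slowly decaying tail past signal offsets that would never cross a
    -60 dB floor on a few-second clip.
    """
    frame_len = max(int(round(frame_ms * w.sample_rate / 1000.0)), 1)
    n_frames = int(np.ceil(w.samples.size / frame_len))
    padded = np.zeros(n_frames * frame_len)
    padded[:w.samples.size] = w.samples
    frames = padded.reshape(n_frames, frame_len)
    frame_rms = np.sqrt(np.mean(frames**2, axis=1))
    peak = frame_rms.max()
    if peak <= 0:
        warnings.warn("clip is entirely silent; pause-corrected RMS undefined",
                      stacklevel=2)
        return 0.0, 1.0
    threshold = peak * 10.0 ** (silence_floor_db / 20.0)
    active = frame_rms >= threshold
    silence_fraction = float(1.0 - active.mean())
    if not active.any():
        warnings.warn("all frames silent under the floor; returning (0, 1)",
                      stacklevel=2)
        return 0.0, 1.0
    mask = np.repeat(active, frame_len)[:w.samples.size]
    rms_active = float(np.sqrt(np.mean(w.samples[mask] ** 2)))
    return rms_active, silence_fraction


def count_steps_over_range(values: np.ndarray, fraction: float = 0.8) -> int:
    """Count indices whose first difference is at least ``fraction`` of the range.

    Shared "number of peaks" rule: a peak is a point exceeding its
    predecessor by at least 80% of the range of the vector. A constant
    vector has zero range and, by convention, zero peaks.
    """
    values = np.asarray(values, dtype=np.float64)
    rng = values.max() - values.min()
    if rng <= 0:
        return 0
    diffs = np.diff(values)
    return int(np.sum(diffs >= fraction * rng))


def count_envelope_peaks(env: Envelope, fraction: float = 0.8) -> int:
    """Number of envelope points rising by >= 80% of the envelope range."""
    if env.values.size < 2:
        raise ValueError("envelope must have at least 2 frames")
    return count_steps_over_range(env.values, fraction)


def burst_episodes(values: np.ndarray, frame_rate: float,
                   min_rise_db: float = 4.0,
                   min_dur_ms: float = 20.0) -> list[Burst]:
    """Episode detector shared by the envelope and modulation-spectrum rules.

    A burst opens when the trace rises at least ``min_rise_db`` above the
    preceding local minimum and closes when it falls back below that
    minimum + ``min_rise_db``; only episodes lasting at least
    ``min_dur_ms`` are kept. The dB reference is the running local
    minimum, so the rule is invariant to global gain.
    """
    v = np.maximum(np.asarray(values, dtype=np.float64), _EPS)
    db = 20.0 * np.log10(v)
    min_frames = max(int(np.ceil(min_dur_ms * frame_rate / 1000.0)), 1)
    bursts: list[Burst] = []
    running_min_db = db[0]
    open_at: int | None = None
    open_ref_db = 0.0
    peak_db = -np.inf
    for i in range(v.size):
        if open_at is None:
            running_min_db = min(running_min_db, db[i])
            if db[i] - running_min_db >= min_rise_db:
                open_at = i
                open_ref_db = running_min_db
                peak_db = db[i]
        else:
            peak_db = max(peak_db, db[i])
            if db[i] < open_ref_db + min_rise_db:
                if i - open_at >= min_frames:
                    bursts.append(Burst(open_at / frame_rate, i / frame_rate,
                                        peak_db - open_ref_db))
                open_at = None
                running_min_db = db[i]
    if open_at is not None and v.size - open_at >= min_frames:
        bursts.append(Burst(open_at / frame_rate, v.size / frame_rate,
                            peak_db - open_ref_db))
    return bursts


def detect_bursts(env: Envelope, min_rise_db: float = 4.0,
                  min_dur_ms: float = 20.0) -> BurstSet:
    """Detect amplitude bursts (>= 4 dB rise lasting >= 20 ms by default)."""
    if min_dur_ms * env.frame_rate / 1000.0 < 2:
        raise ValueError("frame_rate too low to resolve min_dur_ms")
    bursts = burst_episodes(env.values, env.frame_rate, min_rise_db, min_dur_ms)
    return BurstSet(bursts=tuple(bursts), total_duration=env.duration)


def burst_ratio(b: BurstSet) -> float:
    """Total burst duration divided by total clip duration, in [0, 1]."""
    if b.total_duration <= 0:
        raise ValueError("total_duration must be positive")
    covered = sum(x.end - x.start for x in b.bursts)
    return float(covered / b.total_duration)
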