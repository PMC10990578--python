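"""Spectral shape, octave-band energy, centroid dynamics, and flux.

Long-term spectral moments treat the Welch power spectrum as a
probability distribution over frequency: the centroid is the mean,
spread the SD, with standardized skew and excess kurtosis. Octave-band
RMS (centers 63 Hz ... 16 kHz) summarizes the coarse energy layout. The
spectral centroid trajectory over 50 ms windows and its sliding-window
velocity capture spectral drift; spectral flux is the frame-to-frame
Euclidean distance between unit-normalized magnitude spectra, so it is
gain-invariant by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt, welch

from .audio_io import Waveform
from .envelope_features import count_steps_over_range

OCTAVE_CENTERS = (63, 125, 250, 500, 1000, 2000, 4000, 8000, 16000)


class SilentInputError(ValueError):
    """Raised for spectral statistics of an all-zero signal."""


@dataclass(frozen=True)
class Spectrum:
    freqs: np.ndarray
    power: np.ndarray  # density per Hz

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=np.float64)
        p = np.asarray(self.power, dtype=np.float64)
        if np.any(np.diff(f) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("power must be non-negative")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "power", p)


@dataclass(frozen=True)
class CentroidTrack:
    times: np.ndarray
    centroid: np.ndarray


def long_term_spectrum(w: Waveform, nfft: int = 2048) -> Spectrum:
    """Welch power spectral density (Hann, 50% overlap)."""
    nperseg = min(nfft, w.samples.size)
    freqs, power = welch(w.samples, fs=w.sample_rate, window="hann",
                         nperseg=nperseg, noverlap=nperseg // 2, nfft=nfft,
                         detrend=False)
    return Spectrum(freqs=freqs, power=power)


def spectral_moments(s: Spectrum) -> dict[str, float]:
    """Moments of frequency weighted by spectral power, plus the peak count.

    Kurtosis is reported as excess (Gaussian-shaped spectrum -> 0). The
    peak count applies the shared 80%-of-range step rule to the power
    sequence over frequency bins.
    """
    total = s.power.sum()
    if total <= 0:
        raise SilentInputError("cannot compute spectral moments of a silent signal")
    p = s.power / total
    mean = float(np.sum(p * s.freqs))
    var = float(np.sum(p * (s.freqs - mean) ** 2))
    sd = float(np.sqrt(var))
    if sd > 0:
        z = (s.freqs - mean) / sd
        skew = float(np.sum(p * z**3))
        kurt = float(np.sum(p * z**4) - 3.0)
    else:
        skew, kurt = 0.0, 0.0
    return {"spec_centroid": mean, "spec_sd": sd, "spec_skew": skew,
            "spec_kurt": kurt,
            "spec_n_peaks": float(count_steps_over_range(s.power))}


def octave_band_rms(w: Waveform, centers: tuple[float, ...] = OCTAVE_CENTERS
                    ) -> tuple[dict[str, float], list[str]]:
    """Per-band RMS of octave-wide band-pass filtered signal.

    Band edges are center/sqrt(2) to center*sqrt(2) (4th-order
    Butterworth, zero-phase). Bands whose upper edge exceeds Nyquist are
    truncated there and flagged; bands entirely above Nyquist report 0.
    """
    nyq = w.sample_rate / 2.0
    values: dict[str, float] = {}
    flags: list[str] = []
    for fc in centers:
        lo, hi = fc / np.sqrt(2.0), fc * np.sqrt(2.0)
        name = f"band_rms_{int(fc)}"
        if lo >= nyq * 0.999:
            values[name] = 0.0
            flags.append(f"{name}: band above Nyquist, reported 0")
            continue
        if hi > nyq * 0.999:
            hi = nyq * 0.999
            flags.append(f"{name}: upper edge truncated at Nyquist")
        sos = butter(4, [lo, hi], btype="bandpass", fs=w.sample_rate,
                     output="sos")
        band = sosfiltfilt(sos, w.samples)
        values[name] = float(np.sqrt(np.mean(band**2)))
    return values, flags


def _window_centroid(seg: np.ndarray, sr: int) -> float | None:
    """Spectral centroid of one window; None for (near-)silent windows."""
    spec = np.abs(np.fft.rfft(seg * np.hanning(seg.size))) ** 2
    total = spec.sum()
    if total <= 1e-20:
        return None
    freqs = np.fft.rfftfreq(seg.size, 1.0 / sr)
    return float(np.sum(spec * freqs) / total)


def centroid_trajectory(w: Waveform, window_ms: float = 50.0
                        ) -> tuple[CentroidTrack, dict[str, float]]:
    """Per-window centroid over sequential windows, with mean/SD summary.

    Silent windows are excluded from both the track and the summaries;
    an all-silent clip yields an empty track and NaN summaries.
    """
    win = int(round(window_ms * w.sample_rate / 1000.0))
    if w.samples.size < 2 * win:
        raise ValueError("clip must span at least two windows")
    times, cents = [], []
    for start in range(0, w.samples.size - win + 1, win):
        c = _window_centroid(w.samples[start:start + win], w.sample_rate)
        if c is not None:
            times.append((start + win / 2) / w.sample_rate)
            cents.append(c)
    track = CentroidTrack(times=np.array(times), centroid=np.array(cents))
    if not cents:
        return track, {"ctr_mean": float("nan"), "ctr_sd": float("nan"),
                       "all_silent": 1.0}
    arr = np.asarray(cents)
    return track, {"ctr_mean": float(arr.mean()), "ctr_sd": float(arr.std()),
                   "all_silent": 0.0}


def centroid_velocity(w: Waveform, window_ms: float = 50.0,
                      hop_ms: float = 25.0) -> dict[str, float]:
    """Centroid change rate over sliding (overlapping) windows.

    Velocity is the first difference of sliding-window centroids divided
    by the hop; mean and max are taken over |velocity|, SD over the
    signed values.
    """
    sr = w.sample_rate
    win = int(round(window_ms * sr / 1000.0))
    hop = int(round(hop_ms * sr / 1000.0))
    starts = range(0, w.samples.size - win + 1, hop)
    cents = []
    for start in starts:
        c = _window_centroid(w.samples[start:start + win], sr)
        cents.append(np.nan if c is None else c)
    cents_arr = np.asarray(cents, dtype=np.float64)
    if cents_arr.size < 3:
        raise ValueError("need at least 3 sliding windows for velocity")
    vel = np.diff(cents_arr) / (hop / sr)
    vel = vel[np.isfinite(vel)]
    if vel.size == 0:
        return {"vel_mean": 0.0, "vel_sd": 0.0, "vel_max": 0.0}
    return {"vel_mean": float(np.mean(np.abs(vel))),
            "vel_sd": float(np.std(vel)),
            "vel_max": float(np.max(np.abs(vel)))}


def spectral_flux(w: Waveform, frame_ms: float = 25.0, hop_ms: float = 10.0
                  ) -> dict[str, float]:
    """Frame-to-frame change of the unit-normalized magnitude spectrum."""
    sr = w.sample_rate
    win = int(round(frame_ms * sr / 1000.0))
    hop = int(round(hop_ms * sr / 1000.0))
    if w.samples.size < win + hop:
        raise ValueError("need at least 2 frames for spectral flux")
    window = np.hanning(win)
    specs = []
    for start in range(0, w.samples.size - win + 1, hop):
        mag = np.abs(np.fft.rfft(w.samples[start:start + win] * window))
        norm = np.linalg.norm(mag)
        specs.append(mag / norm if norm > 1e-20 else mag * 0.0)
    spec_mat = np.asarray(specs)
    flux = np.linalg.norm(np.diff(spec_mat, axis=0), axis=1)
    return {"flux_mean": float(flux.mean()), "flux_sd": float(flux.std()),
            "flux_max": float(flux.max())}
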