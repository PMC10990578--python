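"""Autocorrelation pitch statistics and correlogram pitch tracking.

Two views of periodicity: global statistics of the normalized
autocorrelation of the whole waveform (how many periodicities, how
strong, how dispersed), and a sliding-window correlogram that tracks
pitch (1 / best lag) and pitch salience (height of the normalized
autocorrelation peak) over 16 ms frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .audio_io import Waveform


@dataclass(frozen=True)
class AutocorrStats:
    n_peaks: int
    max_peak: float
    sd_peaks: float
    range_peaks: float


@dataclass(frozen=True)
class CorrelogramFrame:
    time: float
    pitch: float
    salience: float
    voiced: bool


@dataclass(frozen=True)
class CorrelogramTrack:
    frames: tuple[CorrelogramFrame, ...]
    window_ms: float

    def voiced_frames(self) -> list[CorrelogramFrame]:
        return [f for f in self.frames if f.voiced]


def _autocorr_fft(x: np.ndarray) -> np.ndarray:
    """Biased autocorrelation via FFT, r[0] normalized to 1."""
    n = x.size
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec), nfft)[:n]
    if ac[0] <= 0:
        return np.zeros(n)
    return ac / ac[0]


def autocorrelation_stats(w: Waveform,
                          lag_band: tuple[float, float] = (50.0, 2000.0)
                          ) -> AutocorrStats:
    """Peak statistics of the normalized whole-waveform autocorrelation.

    Peaks are local maxima above zero at lags between 1/max_hz and
    1/min_hz. For an aperiodic signal the statistics approach zero.
    """
    min_hz, max_hz = lag_band
    sr = w.sample_rate
    min_lag = max(int(np.floor(sr / max_hz)), 1)
    max_lag = int(np.ceil(sr / min_hz))
    if w.samples.size < 2 * max_lag:
        raise ValueError("clip too short for the requested lag band")
    ac = _autocorr_fft(w.samples - w.samples.mean())
    segment = ac[min_lag:max_lag + 1]
    idx, _ = find_peaks(segment, height=0.0)
    heights = segment[idx]
    if heights.size == 0:
        return AutocorrStats(0, 0.0, 0.0, 0.0)
    return AutocorrStats(
        n_peaks=int(heights.size),
        max_peak=float(heights.max()),
        sd_peaks=float(np.std(heights)),
        range_peaks=float(heights.max() - heights.min()),
    )


def _ncc_frame(frame: np.ndarray, min_lag: int, max_lag: int
               ) -> tuple[float, float]:
    """Best lag (samples, parabolic-refined) and its normalized correlation.

    Uses overlap-normalized cross-correlation so that a periodic signal
    scores near 1 even when the lag is a large fraction of the window.
    """
    n = frame.size
    x = frame - frame.mean()
    energy = np.cumsum(np.concatenate(([0.0], x * x)))
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    raw = np.fft.irfft(spec * np.conj(spec), nfft)[:n]
    lags = np.arange(min_lag, min(max_lag + 1, n - 1))
    if lags.size == 0:
        return 0.0, 0.0
    e_head = energy[n - lags] - energy[0]
    e_tail = energy[n] - energy[lags]
    denom = np.sqrt(e_head * e_tail)
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = np.where(denom > 0, raw[lags] / denom, 0.0)
    # pick the highest peak; among near-ties (a periodic signal repeats its
    # peak at every period multiple) prefer the shortest lag
    peak_idx, _ = find_peaks(ncc)
    if peak_idx.size == 0:
        peak_idx = np.array([int(np.argmax(ncc))])
    heights = ncc[peak_idx]
    hmax = float(heights.max())
    candidates = peak_idx[heights >= hmax - 0.02]
    k = int(candidates[0])
    best = float(ncc[k])
    lag = float(lags[k])
    if 0 < k < ncc.size - 1:  # parabolic interpolation for sub-sample lag
        y0, y1, y2 = ncc[k - 1], ncc[k], ncc[k + 1]
        denom_p = y0 - 2 * y1 + y2
        if denom_p < 0:
            delta = 0.5 * (y0 - y2) / denom_p
            lag += float(np.clip(delta, -0.5, 0.5))
            best = float(y1 - 0.25 * (y0 - y2) * np.clip(delta, -0.5, 0.5))
    return lag, min(best, 1.0)


def correlogram_track(w: Waveform, window_ms: float = 16.0, hop_ms: float = 8.0,
                      search_band: tuple[float, float] = (80.0, 2000.0),
                      voicing_floor: float = 0.3) -> CorrelogramTrack:
    """Sliding-window pitch/salience track.

    Frames whose peak normalized correlation falls below
    ``voicing_floor`` (or that are effectively silent) are kept but
    flagged unvoiced.
    """
    sr = w.sample_rate
    win = int(round(window_ms * sr / 1000.0))
    hop = max(int(round(hop_ms * sr / 1000.0)), 1)
    if win > w.samples.size:
        raise ValueError("window does not fit the clip")
    lo_hz, hi_hz = search_band
    min_lag = max(int(np.floor(sr / hi_hz)), 1)
    max_lag = int(np.ceil(sr / lo_hz))
    silence_gate = 1e-6 * max(np.max(np.abs(w.samples)), 1e-30)
    frames: list[CorrelogramFrame] = []
    for start in range(0, w.samples.size - win + 1, hop):
        seg = w.samples[start:start + win]
        t = (start + win / 2) / sr
        if np.sqrt(np.mean(seg**2)) <= silence_gate:
            frames.append(CorrelogramFrame(t, 0.0, 0.0, False))
            continue
        lag, sal = _ncc_frame(seg, min_lag, max_lag)
        pitch = sr / lag if lag > 0 else 0.0
        voiced = sal >= voicing_floor and lag > 0
        frames.append(CorrelogramFrame(t, pitch if voiced else pitch,
                                       max(sal, 0.0), voiced))
    return CorrelogramTrack(frames=tuple(frames), window_ms=window_ms)


def correlogram_stats(track: CorrelogramTrack) -> dict[str, float]:
    """Pitch and salience summaries over voiced frames.

    With zero voiced frames all pitch/salience statistics are reported
    as 0 and ``all_unvoiced`` is set.
    """
    voiced = track.voiced_frames()
    if not voiced:
        return {"cg_pitch_mean": 0.0, "cg_pitch_median": 0.0, "cg_pitch_sd": 0.0,
                "cg_pitch_max": 0.0, "cg_sal_mean": 0.0, "cg_sal_max": 0.0,
                "all_unvoiced": 1.0}
    pitches = np.array([f.pitch for f in voiced])
    sals = np.array([f.salience for f in voiced])
    return {
        "cg_pitch_mean": float(pitches.mean()),
        "cg_pitch_median": float(np.median(pitches)),
        "cg_pitch_sd": float(pitches.std()),
        "cg_pitch_max": float(pitches.max()),
        "cg_sal_mean": float(sals.mean()),
        "cg_sal_max": float(sals.max()),
        "all_unvoiced": 0.0,
    }
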