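import numpy as np
import pytest
from scipy.signal import chirp, find_peaks

from audioscene.audio_io import Waveform
from audioscene.spectral_features import (SilentInputError, Spectrum,
                                          centroid_trajectory,
                                          centroid_velocity,
                                          long_term_spectrum, octave_band_rms,
                                          spectral_flux, spectral_moments)
from tests.conftest import SR, make_tone


class TestLongTermSpectrum:
    def test_parseval_within_one_percent(self, rng):
        w = Waveform(rng.normal(0, 0.2, 4 * SR), SR, "n")
        s = long_term_spectrum(w)
        df = s.freqs[1] - s.freqs[0]
        assert np.sum(s.power) * df == pytest.approx(np.mean(w.samples**2),
                                                     rel=0.01)

    def test_sine_has_single_dominant_bin(self):
        s = long_term_spectrum(make_tone(1000, duration=2.0))
        assert abs(s.freqs[np.argmax(s.power)] - 1000) < 10

    def test_two_equal_tones_equal_peaks(self):
        x = make_tone(500, 2.0).samples + make_tone(2000, 2.0).samples
        s = long_term_spectrum(Waveform(x, SR, "2"))
        peaks, props = find_peaks(s.power, height=s.power.max() * 0.1)
        top2 = peaks[np.argsort(props["peak_heights"])[-2:]]
        ratio_db = 10 * np.log10(s.power[top2[0]] / s.power[top2[1]])
        assert abs(ratio_db) < 0.5

    def test_white_noise_flat_within_2db(self, rng):
        acc = None
        for _ in range(100):
            s = long_term_spectrum(Waveform(rng.normal(size=SR), SR, "n"))
            acc = s.power if acc is None else acc + s.power
        band = (s.freqs > 200) & (s.freqs < 7000)
        level = 10 * np.log10(acc[band] / acc[band].mean())
        assert np.all(np.abs(level) < 2.0)


class TestSpectralMoments:
    def test_flat_spectrum_uniform_moments(self):
        freqs = np.linspace(0, 4000, 401)
        m = spectral_moments(Spectrum(freqs=freqs, power=np.ones_like(freqs)))
        assert m["spec_centroid"] == pytest.approx(2000.0)
        assert m["spec_skew"] == pytest.approx(0.0, abs=1e-9)
        # uniform distribution has excess kurtosis -1.2
        assert m["spec_kurt"] == pytest.approx(-1.2, abs=0.02)

    def test_point_mass(self):
        power = np.zeros(100)
        power[37] = 2.0
        m = spectral_moments(Spectrum(freqs=np.arange(100.0) * 10, power=power))
        assert m["spec_centroid"] == 370.0
        assert m["spec_sd"] == 0.0

    def test_two_point_distribution(self):
        freqs = np.array([0.0, 1000.0, 3000.0])
        m = spectral_moments(Spectrum(freqs=freqs,
                                      power=np.array([0.0, 1.0, 1.0])))
        assert m["spec_centroid"] == pytest.approx(2000.0)
        assert m["spec_sd"] == pytest.approx(1000.0)

    def test_silent_input_rejected(self):
        with pytest.raises(SilentInputError):
            spectral_moments(Spectrum(freqs=np.arange(1.0, 5.0),
                                      power=np.zeros(4)))

    def test_centroid_gain_invariant(self, rng):
        w = Waveform(rng.normal(size=SR), SR, "n")
        m1 = spectral_moments(long_term_spectrum(w))
        m2 = spectral_moments(long_term_spectrum(
            Waveform(w.samples * 50, SR, "n2")))
        assert m1["spec_centroid"] == pytest.approx(m2["spec_centroid"],
                                                    rel=1e-9)


class TestOctaveBandRms:
    def test_in_band_tone_dominates_its_band(self):
        w = make_tone(1000, 1.0, sr=32000)
        vals, _ = octave_band_rms(w)
        total = sum(v**2 for v in vals.values())
        assert vals["band_rms_1000"] ** 2 / total >= 0.95

    def test_low_tone_in_lowest_band(self):
        vals, _ = octave_band_rms(make_tone(63, 1.0, sr=32000))
        assert max(vals, key=vals.get) == "band_rms_63"

    def test_white_noise_3db_per_octave(self, rng):
        acc = {}
        for _ in range(10):
            vals, _ = octave_band_rms(Waveform(rng.normal(size=2 * 32000),
                                               32000, "n"))
            for k, v in vals.items():
                acc[k] = acc.get(k, 0.0) + v**2
        for lo, hi in [(125, 250), (250, 500), (500, 1000), (1000, 2000)]:
            ratio_db = 10 * np.log10(acc[f"band_rms_{hi}"] / acc[f"band_rms_{lo}"])
            assert ratio_db == pytest.approx(3.0, abs=0.8)

    def test_nyquist_truncation_flagged(self):
        _, flags = octave_band_rms(make_tone(1000, 0.5, sr=16000))
        assert any("truncated" in f or "above Nyquist" in f for f in flags)

    def test_linear_gain_scaling(self, rng):
        x = rng.normal(size=32000)
        v1, _ = octave_band_rms(Waveform(x, 32000, "a"))
        v2, _ = octave_band_rms(Waveform(3 * x, 32000, "b"))
        for k in v1:
            if v1[k] > 0:
                assert v2[k] / v1[k] == pytest.approx(3.0, rel=1e-6)


class TestCentroidTrajectory:
    def test_steady_tone(self):
        _, summary = centroid_trajectory(make_tone(1000, 1.0))
        assert summary["ctr_mean"] == pytest.approx(1000, rel=0.02)
        assert summary["ctr_sd"] < 30

    def test_alternating_tones_two_point_sd(self):
        seg = int(0.05 * SR)
        blocks = []
        for i in range(40):
            f = 500 if i % 2 == 0 else 2000
            t = np.arange(seg) / SR
            blocks.append(np.sin(2 * np.pi * f * t))
        _, summary = centroid_trajectory(Waveform(np.concatenate(blocks),
                                                  SR, "alt"))
        assert summary["ctr_sd"] == pytest.approx(750, rel=0.1)

    def test_silence_flagged(self):
        track, summary = centroid_trajectory(Waveform(np.zeros(SR), SR, "z"))
        assert summary["all_silent"] == 1.0
        assert track.centroid.size == 0


class TestCentroidVelocity:
    def test_steady_tone_velocity_near_zero(self):
        v = centroid_velocity(make_tone(1000, 1.0))
        assert v["vel_mean"] < 50  # Hz/s; windowing jitter only

    def test_chirp_rate_recovered(self):
        t = np.arange(SR) / SR
        x = chirp(t, f0=500, f1=1500, t1=1.0)
        v = centroid_velocity(Waveform(x, SR, "ch"))
        assert v["vel_mean"] == pytest.approx(1000, rel=0.1)

    def test_step_change_spikes_vel_max(self):
        x = np.concatenate([make_tone(500, 0.5).samples,
                            make_tone(2000, 0.5).samples])
        v = centroid_velocity(Waveform(x, SR, "st"))
        assert v["vel_max"] > 10 * max(v["vel_mean"], 1.0)


class TestSpectralFlux:
    def test_steady_tone_flux_near_zero(self):
        f = spectral_flux(make_tone(1000, 1.0))
        assert f["flux_mean"] < 0.02

    def test_tone_switch_spikes_flux_max(self):
        x = np.concatenate([make_tone(500, 0.5).samples,
                            make_tone(2000, 0.5).samples])
        f = spectral_flux(Waveform(x, SR, "sw"))
        # orthogonal unit spectra differ by sqrt(2); the straddling frame
        # interpolates, so the largest single hop is ~1
        assert f["flux_max"] > 0.9
        assert f["flux_max"] > 20 * f["flux_mean"]

    def test_stationary_noise_flux_stable_across_seeds(self, rng):
        means = [spectral_flux(Waveform(rng.normal(size=SR), SR, "n"))["flux_mean"]
                 for _ in range(20)]
        assert np.std(means) / np.mean(means) < 0.1

    def test_gain_invariance(self, rng):
        x = rng.normal(size=SR)
        f1 = spectral_flux(Waveform(x, SR, "a"))
        f2 = spectral_flux(Waveform(x * 42, SR, "b"))
        assert f1["flux_mean"] == pytest.approx(f2["flux_mean"], rel=1e-9)
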