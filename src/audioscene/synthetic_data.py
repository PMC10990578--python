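"""Synthetic study-condition generators.

Everything the analysis pipeline consumes can be generated here with
known ground truth: 4 s mono audio scenes built from tones, harmonic
complexes, amplitude-modulated noises, burst trains and silence, each
carrying the analytically pinned values of the acoustic measures it
determines; rater panels whose eight property means follow a planted
two-factor structure (two blocks of four properties, mirroring the
two rating groups of 32 and 36 raters) with controllable rater noise and
therefore controllable inter-rater reliability; uniform scene metadata
(temperature, season, indoor/outdoor); and deterministic random-weight
convolutional embedding providers of 14 (event-like) and 19
(setting-like) layers standing in for pretrained networks.

Ratings are discretized by rounding to the nearest integer and clipping
to the 1-7 Likert range. Because clipping and rounding perturb the
continuous-model intraclass correlation, panels generated *for* a target
ICC calibrate the rater noise by numerically inverting the clip+round
observation model (Gauss-Hermite integration, Brent root-finding) rather
than using the continuous closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.signal import butter, sosfiltfilt

from .audio_io import Waveform
from .modulation_features import MOD_UPPER_EDGES
from .rating_stats import SEASON_CATEGORIES, RatingMatrix, SceneTruth
from .spectral_features import OCTAVE_CENTERS

DEFAULT_SAMPLE_RATE = 32000
DEFAULT_DURATION = 4.0

# property names by rating group; the first block loads on factor 1, the
# second on factor 2
GROUP_B_PROPERTIES = ("Season", "Transience", "Navigability", "Sparseness")
GROUP_A_PROPERTIES = ("Open vs. Enclosed", "Outdoor vs. Indoor",
                      "Natural vs. Human-Influenced", "Temperature")
ALL_PROPERTIES = GROUP_B_PROPERTIES + GROUP_A_PROPERTIES

# two-block planted pattern (8 properties x 2 factors)
DEFAULT_LOADINGS = np.array([
    [0.80, 0.0],   # Season
    [0.90, 0.0],   # Transience
    [0.50, 0.0],   # Navigability
    [0.85, 0.0],   # Sparseness
    [0.0, 0.90],   # Open vs. Enclosed
    [0.0, 0.85],   # Outdoor vs. Indoor
    [0.0, 0.60],   # Natural vs. Human-Influenced
    [0.0, 0.50],   # Temperature
])


# ---------------------------------------------------------------------------
# audio scenes

@dataclass(frozen=True)
class Tone:
    freq: float
    amp: float = 0.5
    span: tuple[float, float] | None = None


@dataclass(frozen=True)
class Harmonic:
    f0: float
    n_harm: int = 4
    amp: float = 0.5
    span: tuple[float, float] | None = None


@dataclass(frozen=True)
class SamNoise:
    """Sinusoidally amplitude-modulated band-limited noise."""
    fm: float
    depth: float = 1.0
    band: tuple[float, float] = (500.0, 4000.0)
    amp: float = 0.3
    span: tuple[float, float] | None = None


@dataclass(frozen=True)
class BurstTrain:
    """Baseline noise stepping up by ``rise_db`` in k well-separated bursts."""
    k: int
    rise_db: float = 6.0
    dur_ms: float = 50.0
    base_amp: float = 0.05
    band: tuple[float, float] = (500.0, 4000.0)


@dataclass(frozen=True)
class SceneSpec:
    components: tuple
    duration: float = DEFAULT_DURATION
    sample_rate: int = DEFAULT_SAMPLE_RATE
    seed: int = 0


def _resolve_span(span: tuple[float, float] | None, duration: float
                  ) -> tuple[float, float]:
    if span is None:
        return 0.0, duration
    lo, hi = span
    if not (0.0 <= lo < hi <= duration + 1e-9):
        raise ValueError(f"component span {span} outside the clip")
    return lo, hi


def _band_noise(rng: np.random.Generator, n: int, sr: int,
                band: tuple[float, float]) -> np.ndarray:
    noise = rng.standard_normal(n)
    nyq = sr / 2.0
    lo, hi = band
    sos = butter(4, [max(lo, 1.0), min(hi, nyq * 0.99)], btype="bandpass",
                 fs=sr, output="sos")
    out = sosfiltfilt(sos, noise)
    return out / np.sqrt(np.mean(out**2))


def expected_mod_filter(fm: float) -> float:
    """Upper edge of the octave modulation filter whose band contains fm."""
    for fo in MOD_UPPER_EDGES:
        if fo / 2.0 < fm <= fo:
            return fo
    raise ValueError(f"modulation rate {fm} Hz outside the 0.5-32 Hz filters")


def dominant_octave_band(freq: float) -> int:
    """Octave-band center (Hz) whose band contains ``freq``."""
    for fc in OCTAVE_CENTERS:
        if fc / np.sqrt(2.0) <= freq < fc * np.sqrt(2.0):
            return int(fc)
    raise ValueError(f"{freq} Hz outside the octave filterbank")


def synth_scene(spec: SceneSpec) -> tuple[Waveform, dict[str, float]]:
    """Render a scene and return it with its analytically pinned feature values.

    The ground-truth record holds only values the component mix pins
    down: long-term RMS (before any conditioning), silence fraction
    (fraction of the clip no component covers), fundamental frequency,
    modulation peak frequency (as the containing modulation filter's
    upper edge), burst count, dominant octave band, and spectral
    centroid, whichever apply.
    """
    rng = np.random.default_rng(spec.seed)
    sr = spec.sample_rate
    n = int(round(spec.duration * sr))
    t = np.arange(n) / sr
    x = np.zeros(n)
    covered = np.zeros(n, dtype=bool)
    truth: dict[str, float] = {}
    sq_sum = 0.0
    for comp in spec.components:
        if isinstance(comp, Tone):
            lo, hi = _resolve_span(comp.span, spec.duration)
            i0, i1 = int(round(lo * sr)), int(round(hi * sr))
            phase = rng.uniform(0, 2 * np.pi)
            x[i0:i1] += comp.amp * np.sin(2 * np.pi * comp.freq * t[i0:i1] + phase)
            covered[i0:i1] = True
            frac = (i1 - i0) / n
            sq_sum += comp.amp**2 / 2.0 * frac
            truth.setdefault("f0", comp.freq)
            truth.setdefault("centroid_hz", comp.freq)
            truth.setdefault("dominant_band_hz", dominant_octave_band(comp.freq))
        elif isinstance(comp, Harmonic):
            lo, hi = _resolve_span(comp.span, spec.duration)
            i0, i1 = int(round(lo * sr)), int(round(hi * sr))
            for h in range(1, comp.n_harm + 1):
                a = comp.amp / h
                phase = rng.uniform(0, 2 * np.pi)
                x[i0:i1] += a * np.sin(2 * np.pi * comp.f0 * h * t[i0:i1] + phase)
                sq_sum += a**2 / 2.0 * (i1 - i0) / n
            covered[i0:i1] = True
            truth.setdefault("f0", comp.f0)
        elif isinstance(comp, SamNoise):
            lo, hi = _resolve_span(comp.span, spec.duration)
            i0, i1 = int(round(lo * sr)), int(round(hi * sr))
            carrier = _band_noise(rng, i1 - i0, sr, comp.band)
            mod = 1.0 + comp.depth * np.sin(2 * np.pi * comp.fm * t[i0:i1])
            x[i0:i1] += comp.amp * mod * carrier
            covered[i0:i1] = True
            truth.setdefault("mod_peak_hz", expected_mod_filter(comp.fm))
        elif isinstance(comp, BurstTrain):
            carrier = _band_noise(rng, n, sr, comp.band)
            gain = np.full(n, comp.base_amp)
            step = comp.base_amp * 10.0 ** (comp.rise_db / 20.0)
            dur = int(round(comp.dur_ms * sr / 1000.0))
            gap = (n - comp.k * dur) // (comp.k + 1)
            if gap < dur:
                raise ValueError("burst train does not fit the clip")
            for b in range(comp.k):
                start = gap * (b + 1) + dur * b
                gain[start:start + dur] = step
            x += gain * carrier
            covered[:] = True
            truth.setdefault("n_bursts", float(comp.k))
        else:
            raise ValueError(f"unknown component {comp!r}")
    silence_fraction = float(1.0 - covered.mean())
    truth["silence_fraction"] = silence_fraction
    if sq_sum > 0:
        truth["rms"] = float(np.sqrt(sq_sum))
    w = Waveform(samples=x, sample_rate=sr, scene_id=f"synth{spec.seed:05d}")
    return w, truth


def random_scene_spec(rng: np.random.Generator, duration: float = DEFAULT_DURATION,
                      sample_rate: int = DEFAULT_SAMPLE_RATE) -> SceneSpec:
    """Draw a single-component scene with unambiguous ground truth."""
    kind = rng.integers(0, 5)
    seed = int(rng.integers(0, 2**31 - 1))
    if kind == 0:  # steady tone
        comp = Tone(freq=float(rng.uniform(100, 4000)),
                    amp=float(rng.uniform(0.1, 0.8)))
    elif kind == 1:  # tone with leading/trailing silence
        lo = float(rng.uniform(0.2, duration * 0.4))
        hi = float(rng.uniform(duration * 0.6, duration - 0.2))
        comp = Tone(freq=float(rng.uniform(200, 2000)),
                    amp=float(rng.uniform(0.1, 0.8)), span=(lo, hi))
    elif kind == 2:  # harmonic complex
        comp = Harmonic(f0=float(rng.uniform(100, 400)),
                        n_harm=int(rng.integers(3, 6)),
                        amp=float(rng.uniform(0.2, 0.6)))
    elif kind == 3:  # SAM noise, rate at a modulation-filter band center
        fo = float(MOD_UPPER_EDGES[rng.integers(1, len(MOD_UPPER_EDGES))])
        fm = fo / 2.0 * 2.0 ** 0.5  # geometric center of (fo/2, fo]
        comp = SamNoise(fm=fm, depth=1.0, amp=float(rng.uniform(0.1, 0.5)))
    else:  # burst train
        comp = BurstTrain(k=int(rng.integers(1, 6)),
                          rise_db=float(rng.uniform(6.0, 12.0)),
                          dur_ms=float(rng.uniform(40.0, 120.0)))
    return SceneSpec(components=(comp,), duration=duration,
                     sample_rate=sample_rate, seed=seed)


# ---------------------------------------------------------------------------
# rater panels

@dataclass(frozen=True)
class PanelSpec:
    n_scenes: int = 200
    n_raters: tuple[int, int] = (36, 32)  # (group B, group A)
    loadings: np.ndarray = field(default_factory=lambda: DEFAULT_LOADINGS.copy())
    factor_corr: float = 0.3
    rater_noise_sd: float = 0.5
    rater_bias_sd: float = 0.2
    likert_scale: float = 1.0
    seed: int = 0


def _discretize(values: np.ndarray) -> np.ndarray:
    return np.clip(np.round(values), 1, 7).astype(np.int64)


def synth_panel(spec: PanelSpec
                ) -> tuple[dict[str, RatingMatrix], np.ndarray, np.ndarray]:
    """Generate per-property rating matrices with a planted 2-factor structure.

    Returns (panels, true_factors, true_means): scene factor scores are
    drawn from a correlated two-factor normal model, continuous property
    means are 4 + likert_scale * loadings @ factors, and individual
    ratings add rater bias and noise before round+clip discretization.
    The two 4-property blocks are judged by separate rater groups.
    """
    rng = np.random.default_rng(spec.seed)
    phi = np.array([[1.0, spec.factor_corr], [spec.factor_corr, 1.0]])
    factors = rng.multivariate_normal([0.0, 0.0], phi, size=spec.n_scenes)
    signal = factors @ spec.loadings.T  # scenes x 8
    true_means = 4.0 + spec.likert_scale * signal
    scene_ids = tuple(f"scene{j:04d}" for j in range(spec.n_scenes))
    panels: dict[str, RatingMatrix] = {}
    for p, prop in enumerate(ALL_PROPERTIES):
        k = spec.n_raters[0] if prop in GROUP_B_PROPERTIES else spec.n_raters[1]
        bias = rng.normal(0.0, spec.rater_bias_sd, size=(k, 1))
        noise = rng.normal(0.0, spec.rater_noise_sd,
                           size=(k, spec.n_scenes))
        raw = true_means[:, p][None, :] + bias + noise
        panels[prop] = RatingMatrix(ratings=_discretize(raw),
                                    property_name=prop, scene_ids=scene_ids)
    return panels, factors, true_means


def standardized_loadings(loadings: np.ndarray, noise_sd: float,
                          factor_corr: np.ndarray | None = None) -> np.ndarray:
    """Planted loadings rescaled to unit observed variance.

    EFA standardizes the observed variables, so a recovery check must
    compare against L_i / sqrt((L Phi L')_ii + noise_sd^2).
    """
    loadings = np.asarray(loadings, dtype=np.float64)
    phi = np.eye(loadings.shape[1]) if factor_corr is None \
        else np.asarray(factor_corr)
    total_var = np.sum((loadings @ phi) * loadings, axis=1) + noise_sd**2
    return loadings / np.sqrt(total_var)[:, None]


def planted_factor_data(loadings: np.ndarray, noise_sd: float, n: int,
                        rng: np.random.Generator,
                        factor_corr: np.ndarray | None = None) -> np.ndarray:
    """Continuous observations from a planted factor model (for EFA checks)."""
    loadings = np.asarray(loadings, dtype=np.float64)
    k = loadings.shape[1]
    phi = np.eye(k) if factor_corr is None else np.asarray(factor_corr)
    factors = rng.multivariate_normal(np.zeros(k), phi, size=n)
    return factors @ loadings.T + rng.normal(0.0, noise_sd,
                                             size=(n, loadings.shape[0]))


def _discretized_icc(scene_sd: float, noise_sd: float, k: int,
                     center: float = 4.0, n_quad: int = 61) -> float:
    """Population average-measures consistency ICC under clip+round ratings.

    Scene latent means are N(center, scene_sd^2); a rating is
    clip(round(mu + eps), 1, 7) with eps ~ N(0, noise_sd^2). Integrates
    the first two moments of the discretized rating over the scene
    distribution with Gauss-Hermite quadrature.
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    mus = center + scene_sd * nodes
    wts = weights / weights.sum()
    levels = np.arange(1, 8)
    cuts = np.arange(1.5, 7.0)  # boundaries between rating levels
    cdf = stats.norm.cdf((cuts[None, :] - mus[:, None]) / noise_sd)
    probs = np.diff(np.concatenate(
        [np.zeros((mus.size, 1)), cdf, np.ones((mus.size, 1))], axis=1), axis=1)
    m1 = probs @ levels
    m2 = probs @ (levels**2)
    var_within = float(np.sum(wts * (m2 - m1**2)))
    mean_overall = float(np.sum(wts * m1))
    var_between = float(np.sum(wts * (m1 - mean_overall) ** 2))
    if var_between <= 0:
        return 0.0
    return var_between / (var_between + var_within / k)


def noise_sd_for_icc(target_icc: float, k: int, scene_sd: float = 1.0,
                     center: float = 4.0) -> float:
    """Rater-noise SD whose discretized panel attains the target ICC."""
    if not (0.0 < target_icc < 1.0):
        raise ValueError("target ICC must be in (0, 1)")

    def gap(sigma: float) -> float:
        return _discretized_icc(scene_sd, sigma, k, center) - target_icc

    return float(optimize.brentq(gap, 1e-3, 60.0, xtol=1e-6))


def panel_for_target_icc(target_icc: float, n_scenes: int, n_raters: int,
                         seed: int, scene_sd: float = 1.0,
                         property_name: str = "synthetic") -> RatingMatrix:
    """Single-property panel calibrated to a target ICC(2,k) consistency."""
    rng = np.random.default_rng(seed)
    sigma = noise_sd_for_icc(target_icc, n_raters, scene_sd)
    mus = rng.normal(4.0, scene_sd, size=n_scenes)
    noise = rng.normal(0.0, sigma, size=(n_raters, n_scenes))
    return RatingMatrix(ratings=_discretize(mus[None, :] + noise),
                        property_name=property_name)


# ---------------------------------------------------------------------------
# scene metadata

def synth_metadata(n_scenes: int, seed: int = 0,
                   scene_ids: tuple[str, ...] | None = None) -> list[SceneTruth]:
    """Uniform metadata: temperature on [15, 126] °F, 7 seasons, indoor p=0.5."""
    if n_scenes <= 0:
        raise ValueError("n_scenes must be positive")
    rng = np.random.default_rng(seed)
    ids = scene_ids or tuple(f"scene{j:04d}" for j in range(n_scenes))
    out = []
    for sid in ids:
        out.append(SceneTruth(
            scene_id=sid,
            indoor_outdoor="indoor" if rng.random() < 0.5 else "outdoor",
            season=SEASON_CATEGORIES[rng.integers(0, len(SEASON_CATEGORIES))],
            temperature_f=float(rng.uniform(15.0, 126.0))))
    return out


# ---------------------------------------------------------------------------
# toy embedding providers

class ToyConvProvider:
    """Deterministic random-weight convolutional embedding stack.

    Untrained by design: the probe stage's acceptance is structural
    (planted-signal localization), not replication of any pretrained
    model's fit. Layers apply 3x3 convolutions with tanh nonlinearity;
    time resolution halves on a fixed schedule so receptive fields grow
    with depth, mirroring the coarsening time constants of the networks
    it stands in for (14 event-like layers, 19 setting-like layers).
    """

    _PROFILES = {"event14": ("event", 14, 2), "setting19": ("setting", 19, 3)}

    def __init__(self, profile: str, seed: int = 0, n_kernels: int = 6):
        if profile not in self._PROFILES:
            raise ValueError(f"unknown toy provider profile {profile!r}")
        self.profile = profile
        frontend, n_layers, stride_every = self._PROFILES[profile]
        self.name = f"toy-{profile}"
        self.frontend = frontend
        self.n_layers = n_layers
        self.stride_every = stride_every
        self.n_kernels = n_kernels
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        c_in = 1 if frontend == "event" else 3
        for _ in range(n_layers):
            scale = 1.0 / np.sqrt(9 * c_in)
            self.weights.append(rng.normal(0.0, scale,
                                           size=(3, 3, c_in, n_kernels)))
            c_in = n_kernels

    @staticmethod
    def _conv(x: np.ndarray, w: np.ndarray, stride_t: int) -> np.ndarray:
        padded = np.pad(x, ((1, 1), (1, 1), (0, 0)))
        windows = np.lib.stride_tricks.sliding_window_view(
            padded, (3, 3), axis=(0, 1))  # T x F x C x 3 x 3
        out = np.einsum("tfcij,ijco->tfo", windows, w, optimize=True)
        return np.tanh(out[::stride_t])

    def layer_embeddings(self, w: Waveform) -> list[np.ndarray]:
        from .embedding_probe import mel_frontend

        x = mel_frontend(w, self.frontend)
        outputs = []
        for li, kernel in enumerate(self.weights):
            stride = 2 if (li + 1) % self.stride_every == 0 and x.shape[0] >= 4 else 1
            x = self._conv(x, kernel, stride)
            outputs.append(x)
        return outputs


def toy_provider(profile: str, seed: int = 0) -> ToyConvProvider:
    """Factory for the event-like (14-layer) / setting-like (19-layer) fixtures."""
    return ToyConvProvider(profile, seed)


PROVIDER_REGISTRY = {
    "toy-event14": lambda seed=0: toy_provider("event14", seed),
    "toy-setting19": lambda seed=0: toy_provider("setting19", seed),
}
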