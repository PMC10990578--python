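"""Layer-wise linear probing of deep audio-scene embeddings.

A provider maps a waveform to an ordered list of time x frequency x
kernel tensors, one per convolutional layer (shallow to deep). Each
layer is integrated over time to a kernel x frequency matrix, flattened
across scenes, reduced with PCA to a common dimensionality D (136 by
default, chosen to retain at least 90% of embedding variance), and
regressed onto mean property ratings. Per-layer adjusted R^2 against a
relative depth scale ((l-1)/(n_layers-1)) supports comparison across
architectures of different depth; significant layer values are fitted
with a bi-quadratic (degree-4) polynomial to locate the depth at which a
property is best decoded, and aggregate (all layers, second PCA)
adjusted R^2 differences between models are reported in percentage
points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.signal import stft

from .audio_io import Waveform, resample
from .regression_mapping import adjusted_r2

DEFAULT_PCA_DIM = 136


class EmbeddingProvider(Protocol):
    """Deterministic multi-layer embedding extractor."""

    name: str
    n_layers: int

    def layer_embeddings(self, w: Waveform) -> list[np.ndarray]:
        """Ordered (shallow -> deep) list of time x frequency x kernel tensors."""
        ...


@dataclass(frozen=True)
class LayerEmbedding:
    layer_index: int          # 1-based
    matrix: np.ndarray        # kernels x frequency, time-integrated


@dataclass(frozen=True)
class LayerResult:
    layer_index: int
    relative_depth: float
    r2_adj: float
    p_value: float


@dataclass(frozen=True)
class LayerProfile:
    model_name: str
    property_name: str
    layers: tuple[LayerResult, ...]


@dataclass(frozen=True)
class DepthCurveFit:
    coefficients: np.ndarray  # ascending powers, degree 4
    peak_depth: float
    n_points_used: int


# ---------------------------------------------------------------------------
# front ends

def _hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, nfft: int, sr: int, fmin: float, fmax: float
                   ) -> np.ndarray:
    """Triangular mel filterbank (n_mels x nfft//2 + 1)."""
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = np.asarray(_mel_to_hz(mel_pts))
    bins = np.fft.rfftfreq(nfft, 1.0 / sr)
    fb = np.zeros((n_mels, bins.size))
    for i in range(n_mels):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (bins - lo) / max(ctr - lo, 1e-9)
        down = (hi - bins) / max(hi - ctr, 1e-9)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def _log_mel(w: Waveform, sr: int, win_s: float, hop_s: float, n_mels: int,
             fmin: float, fmax: float, nfft: int | None = None) -> np.ndarray:
    """time x mel log-magnitude map."""
    x = resample(w, sr) if w.sample_rate != sr else w
    win = int(round(win_s * sr))
    hop = int(round(hop_s * sr))
    nfft = nfft or (1 << int(np.ceil(np.log2(win))))
    _, _, z = stft(x.samples, fs=sr, window="hann", nperseg=win,
                   noverlap=win - hop, nfft=nfft, boundary=None, padded=False)
    power = np.abs(z.T) ** 2  # time x freq
    fb = mel_filterbank(n_mels, nfft, sr, fmin, fmax)
    mel = power @ fb.T
    return np.log(mel + 1e-10)


def mel_frontend(w: Waveform, profile: str) -> np.ndarray:
    """Network input feature map for the ``event`` or ``setting`` profile.

    event: 16 kHz, peak-normalized to [-1, 1], 25 ms Hann window / 10 ms
    hop, 64 mel bins over 125-7500 Hz, segmented into 1 s windows sampled
    to 96 frames each; output (n_segments * 96) x 64 x 1.

    setting: 44.1 kHz, 2048-point FFT with 46 ms window / 23 ms hop, 128
    log-mel bins min-max normalized to [0, 1] along frequency, augmented
    with delta and delta-delta channels; output time x 128 x 3.
    """
    if profile == "event":
        x = resample(w, 16000) if w.sample_rate != 16000 else w
        peak = np.max(np.abs(x.samples))
        if peak > 0:
            x = Waveform(x.samples / peak, 16000, x.scene_id)
        mel = _log_mel(x, 16000, 0.025, 0.010, 64, 125.0, 7500.0)
        # one segment per second of audio; window-edge loss means slightly
        # fewer than 100 frames per second, so segment by equal division
        n_segments = int(round(x.duration))
        if n_segments < 1 or mel.shape[0] < 48:
            raise ValueError("clip shorter than one 1-second segment")
        bounds = np.linspace(0, mel.shape[0], n_segments + 1).round().astype(int)
        segs = []
        for s in range(n_segments):
            block = mel[bounds[s]:bounds[s + 1]]
            idx = np.linspace(0, block.shape[0] - 1, 96).round().astype(int)
            segs.append(block[idx])
        return np.concatenate(segs, axis=0)[:, :, None]
    if profile == "setting":
        mel = _log_mel(w, 44100, 0.046, 0.023, 128, 0.0, 22050.0, nfft=2048)
        lo, hi = mel.min(axis=1, keepdims=True), mel.max(axis=1, keepdims=True)
        span = np.where(hi - lo > 1e-12, hi - lo, 1.0)
        static = (mel - lo) / span
        delta = np.gradient(static, axis=0)
        ddelta = np.gradient(delta, axis=0)
        return np.stack([static, delta, ddelta], axis=-1)
    raise ValueError(f"unknown frontend profile {profile!r}")


# ---------------------------------------------------------------------------
# probing machinery

def integrate_time(tensor: np.ndarray, layer_index: int = 1) -> LayerEmbedding:
    """Mean over the time axis of a time x frequency x kernel tensor."""
    t = np.asarray(tensor, dtype=np.float64)
    if t.ndim != 3 or t.shape[0] == 0:
        raise ValueError("expected a non-empty time x frequency x kernel tensor")
    return LayerEmbedding(layer_index=layer_index, matrix=t.mean(axis=0).T)


def reduce_pca(embeddings: np.ndarray, d: int = DEFAULT_PCA_DIM,
               seed: int | None = 0) -> tuple[np.ndarray, float, bool]:
    """Centered PCA scores plus captured-variance share.

    ``d`` is truncated (with a flag) when it exceeds what the data can
    support; a warning is issued when the captured variance falls below
    the 90% criterion used to choose D.
    """
    from sklearn.decomposition import PCA

    x = np.asarray(embeddings, dtype=np.float64)
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 scenes")
    if not np.any(x.std(axis=0) > 0):
        raise ValueError("zero-variance input to PCA")
    d_max = min(x.shape[0], x.shape[1])
    truncated = d > d_max
    d_eff = min(d, d_max)
    pca = PCA(n_components=d_eff, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(x)
    captured = float(pca.explained_variance_ratio_.sum())
    if captured < 0.90:
        warnings.warn(f"PCA captured {captured:.1%} < 90% of variance at d={d_eff}",
                      stacklevel=2)
    return scores, captured, truncated


def _ols_r2adj(scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Adjusted R^2 and model-F p-value of y on the score matrix."""
    n, p = scores.shape
    if n <= p + 1:
        raise ValueError(f"scenes ({n}) must exceed predictors + 1 ({p + 1})")
    model = sm.OLS(y, sm.add_constant(scores)).fit()
    return adjusted_r2(model.rsquared, n, p), float(model.f_pvalue)


def _cap_dim(d: int, n_scenes: int) -> int:
    if d > n_scenes - 2:
        warnings.warn(f"PCA dimension capped at {n_scenes - 2} for {n_scenes} scenes",
                      stacklevel=3)
        return n_scenes - 2
    return d


def layer_feature_matrices(provider: EmbeddingProvider,
                           scenes: Sequence[Waveform]) -> list[np.ndarray]:
    """Per-layer scenes x flattened(K x F) feature matrices."""
    per_layer: list[list[np.ndarray]] = [[] for _ in range(provider.n_layers)]
    for w in scenes:
        tensors = provider.layer_embeddings(w)
        if len(tensors) != provider.n_layers:
            raise ValueError("provider returned an unexpected layer count")
        for li, tensor in enumerate(tensors):
            per_layer[li].append(integrate_time(tensor, li + 1).matrix.ravel())
    return [np.vstack(rows) for rows in per_layer]


def layer_score_matrices(layer_mats: Sequence[np.ndarray],
                         d: int = DEFAULT_PCA_DIM,
                         seed: int | None = 0) -> list[np.ndarray]:
    """PCA scores per layer, dimension capped by scene count."""
    n = layer_mats[0].shape[0]
    d_eff = _cap_dim(d, n)
    return [reduce_pca(m, d_eff, seed)[0] for m in layer_mats]


def layerwise_regression_from_scores(scores: Sequence[np.ndarray],
                                     property_means: np.ndarray,
                                     model_name: str = "",
                                     property_name: str = "") -> LayerProfile:
    """Per-layer adjusted R^2 profile from precomputed PCA scores."""
    y = np.asarray(property_means, dtype=np.float64)
    n_layers = len(scores)
    layers = []
    for li, s in enumerate(scores):
        try:
            r2a, p = _ols_r2adj(s, y)
        except Exception as exc:
            raise RuntimeError(f"probe regression failed at layer {li + 1}: {exc}"
                               ) from exc
        layers.append(LayerResult(layer_index=li + 1,
                                  relative_depth=relative_depth(li + 1, n_layers),
                                  r2_adj=r2a, p_value=p))
    return LayerProfile(model_name=model_name, property_name=property_name,
                        layers=tuple(layers))


def layerwise_regression(provider: EmbeddingProvider, scenes: Sequence[Waveform],
                         property_means: np.ndarray, d: int = DEFAULT_PCA_DIM,
                         seed: int | None = 0,
                         property_name: str = "") -> LayerProfile:
    """Full per-layer probe: embed, integrate, PCA, regress."""
    mats = layer_feature_matrices(provider, scenes)
    scores = layer_score_matrices(mats, d, seed)
    return layerwise_regression_from_scores(scores, property_means,
                                            model_name=provider.name,
                                            property_name=property_name)


def aggregate_regression_from_scores(scores: Sequence[np.ndarray],
                                     property_means: np.ndarray,
                                     d: int = DEFAULT_PCA_DIM,
                                     seed: int | None = 0) -> float:
    """Aggregate adjusted R^2: concatenate per-layer scores, second PCA, OLS."""
    stacked = np.hstack(list(scores))
    d_eff = _cap_dim(d, stacked.shape[0])
    reduced, _, _ = reduce_pca(stacked, d_eff, seed)
    y = np.asarray(property_means, dtype=np.float64)
    r2a, _ = _ols_r2adj(reduced, y)
    return r2a


def aggregate_regression(provider: EmbeddingProvider, scenes: Sequence[Waveform],
                         property_means: np.ndarray, d: int = DEFAULT_PCA_DIM,
                         seed: int | None = 0) -> float:
    mats = layer_feature_matrices(provider, scenes)
    scores = layer_score_matrices(mats, d, seed)
    return aggregate_regression_from_scores(scores, property_means, d, seed)


def relative_depth(l: int, n_layers: int) -> float:
    """Map layer index to [0, 1]: 0 = shallowest, 1 = deepest."""
    if n_layers < 2 or not (1 <= l <= n_layers):
        raise ValueError("need 1 <= l <= n_layers and n_layers >= 2")
    return (l - 1) / (n_layers - 1)


def fit_depth_curve(profile: LayerProfile, alpha: float = 0.05) -> DepthCurveFit:
    """Bi-quadratic (degree-4) fit of adjusted R^2 over relative depth.

    Only layers whose probe regression is significant at ``alpha`` enter
    the fit; the reported peak is the argmax of the fitted polynomial on
    [0, 1].
    """
    pts = [(lr.relative_depth, lr.r2_adj) for lr in profile.layers
           if lr.p_value < alpha]
    if len(pts) < 5:
        raise ValueError(
            f"only {len(pts)} significant layers; a degree-4 fit needs >= 5 "
            "(consider a lower-degree fallback)")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    coeffs = np.polynomial.polynomial.polyfit(x, y, 4)
    poly = np.polynomial.Polynomial(coeffs)
    crit = [0.0, 1.0]
    for root in poly.deriv().roots():
        if abs(root.imag) < 1e-9 and 0.0 <= root.real <= 1.0:
            crit.append(float(root.real))
    peak = max(crit, key=lambda t: poly(t))
    return DepthCurveFit(coefficients=coeffs, peak_depth=float(peak),
                         n_points_used=len(pts))


def delta_r2(model_a_r2_adj: float, model_b_r2_adj: float) -> float:
    """Difference in aggregate adjusted R^2, in percentage points (a - b)."""
    return 100.0 * (model_a_r2_adj - model_b_r2_adj)
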