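# Methods

This note documents the models and estimators implemented in `audioscene`,
the parameter choices that matter, and the design decisions taken where the
conventions of the field leave the procedure open.

## Audio conditioning

Scenes are mono float waveforms in nominal [−1, 1]. Stimulus conditioning
matches common psychoacoustic practice: RMS matching to a configurable target
(default 0.05 full scale) and 10 ms linear onset/offset ramps. Multichannel
WAV input is averaged to mono. Resampling is polyphase band-limited
(`scipy.signal.resample_poly`); a resampled tone keeps its frequency within
1 Hz.

## Envelope measures

The amplitude envelope is the magnitude of the analytic signal, smoothed and
sampled at 1 kHz. Two numerical choices matter:

- **Positive smoothing kernel.** Smoothing uses a zero-phase Hann kernel of
  duration ≈ 1/cutoff (default cutoff 30 Hz) rather than an IIR low-pass. A
  positive kernel has a monotone step response: a Butterworth low-pass
  undershoots after an amplitude offset, and in dB that undershoot registers
  as a spurious ≥ 4 dB "rise" that the burst detector would count. The signal
  is zero-padded before the FFT-based analytic transform because its circular
  extension otherwise wraps edge ringing to the opposite end of the clip, and
  20 ms is trimmed from each end of the envelope to discard edge transients.
- **Frame-RMS silence gating.** Pause correction classifies 10 ms frames as
  silent when their RMS falls 60 dB below the loudest frame. Frame RMS rather
  than the analytic envelope is used here because the Hilbert envelope leaks
  a slowly decaying (≈ 1/t) tail past signal offsets; on a 4 s clip that tail
  never crosses a −60 dB floor, so digital silence would never be detected.

Bursts follow the classic rule: an episode opens when the envelope rises at
least 4 dB above the preceding local minimum, closes when it falls back below
that minimum + 4 dB, and is kept if it lasts at least 20 ms. The dB reference
is the running local minimum, making detection gain-invariant. Envelope
"peaks" are points exceeding their predecessor by at least 80 % of the
envelope's range; a constant envelope has zero peaks by convention.

## Pitch measures

Whole-waveform autocorrelation statistics use the biased, zero-lag-normalized
autocorrelation restricted to lags between 1/2000 and 1/50 s; peaks are local
maxima above zero, summarized by count, maximum, SD, and range (the latter two
are near zero for a pure tone, whose period-multiple peaks differ only by the
slow windowing decay).

The correlogram tracks pitch in sliding 16 ms windows with 8 ms hop.
Frames use rectangular windows with overlap-normalized cross-correlation
(dividing by the energies of the two overlapping segments), not a Hann taper:
with a 16 ms window and candidate lags up to 12.5 ms (80 Hz floor), tapering
biases the peak correlation of a perfectly periodic frame well below 1,
breaking the salience scale. Among near-tied peaks (a periodic signal repeats
its peak at every period multiple) the shortest lag wins, with parabolic
interpolation for sub-sample lags. Frames whose peak correlation falls below
the voicing floor (0.3, configurable) are kept but flagged unvoiced; pitch
statistics summarize voiced frames only, and an all-unvoiced track reports
zeros with a flag. The 16 ms window bounds the measurable floor, hence the
80–2000 Hz search band.

## Spectral measures

The long-term spectrum is Welch-averaged (Hann, 50 % overlap, 2048-point FFT
at 16–32 kHz rates) and satisfies Parseval within 1 %. Spectral moments treat
power over linear frequency as a probability mass: centroid (mean), SD,
standardized skew, and excess kurtosis (Gaussian-shaped spectrum → 0); the
"number of peaks" applies the 80 %-of-range step rule to the power sequence.
Octave-band RMS uses 4th-order zero-phase Butterworth band-passes with edges
fc/√2 … fc·√2 at centers 63–16000 Hz; bands crossing Nyquist are truncated
there and flagged. Centroid mean/SD come from sequential 50 ms windows
(silent windows excluded); centroid velocity from sliding 50 ms windows with
25 ms hop, first-differenced and divided by the hop, with mean and max over
|velocity| and SD over signed values. Spectral flux is the Euclidean distance
between successive unit-normalized magnitude spectra (25 ms frames, 10 ms
hop), which makes it gain-invariant; full-band flux is the roster measure.

## Modulation spectrum

Carrier decomposition uses 1/3-octave band-passes from 125 to 8000 Hz as the
"approximately one critical band" bank. Per band, the envelope (magnitude of
the analytic signal) is reduced to a modulation depth per octave modulation
filter with upper edges {1, 2, 4, 8, 16, 32} Hz. Depth is estimated
spectrally: the envelope periodogram is integrated over (f_o/2, f_o] and
depth = √(2·power)/mean(envelope), which recovers the modulation index m of
sinusoidal AM exactly and is invariant to global gain. A spectral estimate is
used because time-domain 0.5–1 Hz band-pass filters ring for a substantial
fraction of a 4 s record. Depths are pooled over carrier bands by unweighted
mean. One consequence documented deliberately: for unmodulated noise the
pooled depth grows ≈ √f_o with the octave filters' bandwidth rather than
being flat; the summary statistics (height and frequency of the pooled
maximum; burst count/mean/variance of the pooled vector under the 4 dB rule
with a minimum run of one point, since a 6-point frequency axis cannot
express a 20 ms clause) are insensitive to this baseline tilt for modulated
scenes.

## Feature roster

43 measures are computed; the default roster exposes 35 columns, dropping
eight near-duplicate or low-variance companions (silence fraction — a
monotone companion of pause-corrected RMS; autocorrelation peak count; median
pitch; windowed centroid mean/SD, which duplicate the long-term centroid on
stationary scenes; flux maximum; modulation burst mean/variance, near-
degenerate on a 6-point axis). Roster membership is a config choice
(`features.roster: default | extended`); total duration is computed but
off-roster since the study's scenes share one duration.

## Rating statistics

ICC(2,k) follows the two-way, consistency, average-measures mean-squares
form: with scenes as targets and raters as columns,
ICC = (MS_R − MS_E)/MS_R, F = MS_R/MS_E on (n−1, (n−1)(k−1)) df, with the
standard F-quantile 95 % interval. The consistency definition discards rater
main effects, so rater-specific constant offsets do not change the
coefficient. Property correlations are Pearson with t-distributed p-values on
n−2 df and no multiplicity correction by default (a Holm option exists).
Temperature accuracy bins both the 1–7 rating and the true temperature into
seven 15 °F bins starting at 15, 31, 47, 63, 79, 95, 111 °F; season compares
seven categories (the administered scale has no "Between Fall and Winter"
option); outdoor/indoor dichotomizes ratings 1–3 vs 5–7 with the midpoint 4
excluded by default (nearest-low / nearest-high policies available). Chance
is 100/#categories: 14.29 % for the seven-way schemes, 50 % dichotomous.

## Factor analysis

KMO is computed from correlations vs anti-image partial correlations;
Bartlett's sphericity is χ² = −(n−1−(2p+5)/6)·ln det R on p(p−1)/2 df.
Parallel analysis compares principal-component eigenvalues of the observed
correlation matrix against the 95th percentile of eigenvalues from
independent standard-normal data of identical shape (1000 simulations by
default); the suggested count is the leading run of observed eigenvalues
above their rank-matched quantile. Because the simulated quantiles depend
only on the data shape, they can be computed once and reused across datasets
of the same shape. Extraction is maximum likelihood (via
`statsmodels.multivariate.factor`) with oblimin rotation by default and
geomin exposed; factor signs are canonicalized (largest |loading| positive)
and factors ordered by explained variance. Variance shares are
structure-weighted sums of squares, diag(PᵀPΦ)/p, which sum to the mean
communality. Heywood cases are clamped at communality 0.999 with a warning.
Display tables blank loadings below |.40| and order variables by dominant
factor, then magnitude. Recovery checks compare against *standardized*
planted loadings (L scaled to unit observed variance), aligned by a greedy
congruence-maximizing permutation with sign flips.

## Regressions

Each property's mean rating is regressed on the z-scored roster (simultaneous
entry, no stepwise); coefficients are therefore standardized betas.
Known near-duplicates (overall vs pause-corrected RMS) stay in the design —
their opposite-signed large betas are themselves informative — and a
variance-inflation report is emitted as a warning rather than dropping
columns. Exact rank deficiency raises an error naming the collinear columns.
Significance is two-sided at α = 0.05 without multiplicity correction. The
orchestration layer screens zero-variance and exactly collinear columns and
caps the predictor count below n − 2 for small synthetic runs.

## Embedding probe

Providers return one time × frequency × kernel tensor per layer, shallow to
deep. Two front-end profiles are implemented: *event* (16 kHz, peak
normalization to [−1, 1], 25 ms Hann / 10 ms hop, 64 mel bins over
125–7500 Hz — the mel filterbank is implemented in-package since no
mel-spectrogram library is available — segmented per second into 96 frames)
and *setting* (44.1 kHz, 2048-point FFT, 46 ms window / 23 ms hop, 128
log-mel bins min-max normalized over frequency, plus delta and delta-delta
channels). Each layer is integrated over time to kernels × frequency,
flattened across scenes, and reduced by PCA fitted jointly across scenes
(study-scale default D = 136, chosen to retain ≥ 90 % of embedding variance;
a checker warns below that). D is capped at scenes − 2 with a warning when
the scene count cannot support it. Per-layer OLS of the property means on the
scores yields adjusted R² and a model-F p-value (the F-test is the
significance criterion for depth-curve inclusion); the aggregate measure
concatenates per-layer scores and applies a second PCA to D before the
regression. Layer indices map to relative depth (l−1)/(n_layers−1). The
depth curve is a least-squares degree-4 ("bi-quadratic") polynomial over
significant layers (≥ 5 required), with the peak taken as the argmax on
[0, 1]; ΔR² between models is reported in percentage points.

The bundled providers are deterministic random-weight convolutional stacks
(3×3 kernels, tanh, time-stride schedule that halves resolution every 2nd or
3rd layer) of 14 (event-like) and 19 (setting-like) layers. The 19 reflects a
17 + 2 reading of the setting architecture's convolutional depth; the
relative-depth scale absorbs the difference. They are untrained by design:
the probe stage's validation is structural — when an outcome is planted in
layer j's leading PCA scores, the per-layer adjusted-R² argmax must find
layer j — not a replication of any pretrained model's absolute fits. The
structural localization harness uses probe dimension 20 at 200 scenes;
with D = 136 and n = 200 the per-layer regressions are barely determined and
adjacent-layer fits tie within estimation noise, which is a property of that
n/D ratio, not of the probe machinery.

## Synthetic study conditions

Scene components pin exactly the features they determine: tones and harmonic
complexes pin f0, spectral centroid, octave band, and RMS; spans pin the
silence fraction; SAM noises pin the modulation filter containing the
modulation rate; burst trains pin the burst count. The default scene is 4 s
at 32 kHz. Recovery tolerances: RMS 2 % relative, silence fraction ±0.02,
f0 3 % relative, centroid 5 % relative, modulation filter / burst count /
dominant band exact.

Rater panels follow a planted two-factor model: scene factor scores are
bivariate normal with correlation 0.3, property means are
4 + loadings·factors over two 4-property blocks (mirroring two rating groups
of 36 and 32 raters), and individual ratings add rater bias (SD 0.2) and
noise before round-and-clip discretization to 1–7. Discretization perturbs
the continuous-model ICC, so panels generated *for* a target ICC calibrate
the rater-noise SD by numerically inverting the clip+round observation model
(Gauss–Hermite integration over the scene distribution, Brent root-finding);
the calibration is deterministic and part of the generator's definition.
Metadata is uniform: temperature on [15, 126] °F, seven seasons,
indoor/outdoor Bernoulli(0.5).

What passing these harnesses shows — and does not. The synthetic scenes
exercise every estimator against constructions with closed-form truth, and
the panels exercise the inferential chain at the study's n and k. They do not
emulate the semantic content or the acoustic richness of real recordings
(overlapping sources, reverberation, nonstationary backgrounds), so recovery
rates here bound estimator correctness, not field performance; and the toy
providers say nothing about what pretrained event- or setting-classification
networks encode.

## Problem sizes

The test suite and the validation script run at: 200 scenes for feature
recovery; 1000 random matrices for the ICC oracle; 100 seeds × (200 scenes ×
30 raters) per calibrated reliability target; 100 seeds for each
parallel-analysis selection rate (with shape-shared simulated quantiles at
1000 simulations); 50 seeds for loading recovery; 100 random designs for the
OLS oracle and 100 null seeds (2000 coefficient tests) for type-I
calibration; 200 scenes × 50 trials for probe localization; 100 noisy
replicates for depth-curve recovery. A complete run takes about a minute on
one core.
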