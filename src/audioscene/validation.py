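"""End-to-end validation harnesses with known ground truth.

Each function regenerates its own synthetic study conditions from a seed,
runs the corresponding pipeline stage, and returns a summary quantity:
Monte-Carlo chance levels, the acoustic feature-recovery rate, agreement
of the ICC implementation with an explicit ANOVA oracle and recovery of
calibrated panel reliabilities, parallel-analysis factor-count selection
rates, planted-loading recovery error, the OLS oracle gap and type-I
error rate, planted-signal layer localization, and depth-curve peak
recovery. These are the package's structural correctness measures; they
are what the test suite asserts against.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import embedding_probe as ep
from .factor_analysis import (align_loadings, fit_efa, parallel_analysis,
                              simulate_pa_quantiles)
from .feature_table import verify_scene_truth
from .rating_stats import RatingMatrix, icc_2k, percent_correct
from .regression_mapping import fit_property_regression
from .synthetic_data import (DEFAULT_LOADINGS, PanelSpec,
                             panel_for_target_icc, planted_factor_data,
                             random_scene_spec, standardized_loadings,
                             synth_metadata, synth_panel, synth_scene)


def chance_monte_carlo(scheme: str, n_raters: int = 1000, n_scenes: int = 200,
                       seed: int = 0) -> float:
    """Mean percent-correct of raters answering uniformly at random."""
    rng = np.random.default_rng(seed)
    truth = synth_metadata(n_scenes, seed=int(rng.integers(2**31)))
    ratings = rng.integers(1, 8, size=(n_raters, n_scenes))
    m = RatingMatrix(ratings, scheme, tuple(t.scene_id for t in truth))
    return percent_correct(m, truth, scheme)["mean"]


def feature_recovery_rate(n_scenes: int = 200, seed: int = 0
                          ) -> tuple[float, int]:
    """Fraction (%) of pinned ground-truth values recovered, and the count."""
    rng = np.random.default_rng(seed)
    passed = total = 0
    for _ in range(n_scenes):
        results = verify_scene_truth(random_scene_spec(rng))
        for _, (_, _, ok) in results.items():
            total += 1
            passed += ok
    return 100.0 * passed / total, total


def _anova_icc(ratings: np.ndarray) -> float:
    """Explicit two-way ANOVA mean-squares oracle."""
    x = np.asarray(ratings, float).T
    n, k = x.shape
    grand = x.mean()
    ss_rows = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_err = ((x - grand) ** 2).sum() - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / ms_r


def icc_oracle_max_diff(n_matrices: int = 1000, seed: int = 0) -> float:
    """Largest |ICC - ANOVA oracle| over random complete rating matrices."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n_matrices:
        k = int(rng.integers(3, 9))
        n = int(rng.integers(4, 20))
        ratings = rng.integers(1, 8, size=(k, n))
        m = RatingMatrix(ratings, "x")
        oracle = _anova_icc(ratings)
        if not np.isfinite(oracle) or ratings.std(axis=0).sum() == 0:
            continue
        try:
            est = icc_2k(m).icc
        except ValueError:
            continue
        worst = max(worst, abs(est - oracle))
        done += 1
    return worst


def planted_icc_recovery(targets=(0.3, 0.6, 0.9), n_seeds: int = 100,
                         n_scenes: int = 200, n_raters: int = 30,
                         seed: int = 0) -> dict[float, float]:
    """Mean estimated ICC per calibrated target over seeds."""
    rng = np.random.default_rng(seed)
    out = {}
    for target in targets:
        vals = [icc_2k(panel_for_target_icc(
            target, n_scenes, n_raters, seed=int(rng.integers(2**31)))).icc
            for _ in range(n_seeds)]
        out[target] = float(np.mean(vals))
    return out


def pa_panel_selection_rate(n_seeds: int = 100, n_scenes: int = 200,
                            seed: int = 0, n_sims: int = 1000) -> float:
    """% of seeds where parallel analysis finds 2 factors in panel means."""
    rng = np.random.default_rng(seed)
    quantiles = simulate_pa_quantiles(n_scenes, 8, n_sims=n_sims,
                                      seed=int(rng.integers(2**31)))
    hits = 0
    for _ in range(n_seeds):
        panels, _, _ = synth_panel(PanelSpec(
            n_scenes=n_scenes, seed=int(rng.integers(2**31))))
        means = np.column_stack([m.scene_means() for m in panels.values()])
        hits += parallel_analysis(means, sim_quantiles=quantiles).suggested_n == 2
    return 100.0 * hits / n_seeds


SEVEN_FACTOR_LOADINGS = np.kron(np.eye(7), np.full((5, 1), 0.75))


def pa_acoustic_selection_rate(n_seeds: int = 100, n_scenes: int = 200,
                               seed: int = 0, n_sims: int = 1000) -> float:
    """% of seeds where PA finds 7 factors in a 35-variable planted design."""
    rng = np.random.default_rng(seed)
    quantiles = simulate_pa_quantiles(n_scenes, 35, n_sims=n_sims,
                                      seed=int(rng.integers(2**31)))
    hits = 0
    for _ in range(n_seeds):
        data = planted_factor_data(SEVEN_FACTOR_LOADINGS, 0.5, n_scenes, rng)
        hits += parallel_analysis(data, sim_quantiles=quantiles).suggested_n == 7
    return 100.0 * hits / n_seeds


TWO_FACTOR_LOADINGS = np.array(
    [[0.8, 0.0], [0.8, 0.0], [0.7, 0.0], [0.7, 0.0],
     [0.0, 0.8], [0.0, 0.8], [0.0, 0.7], [0.0, 0.7]])


def efa_recovery_failure_rate(n_seeds: int = 50, n_scenes: int = 200,
                              seed: int = 0, tol: float = 0.1
                              ) -> tuple[float, float]:
    """(% of seeds with any |loading error| > tol, mean max error).

    Planted two-factor design with noise SD 0.5; estimated pattern is
    aligned by congruence before comparison against the standardized
    planted loadings.
    """
    rng = np.random.default_rng(seed)
    target = standardized_loadings(TWO_FACTOR_LOADINGS, 0.5)
    failures = 0
    max_errs = []
    for _ in range(n_seeds):
        data = planted_factor_data(TWO_FACTOR_LOADINGS, 0.5, n_scenes, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_efa(data, 2)
        aligned, _, _ = align_loadings(res.loadings.to_numpy(), target)
        err = float(np.max(np.abs(aligned - target)))
        max_errs.append(err)
        failures += err > tol
    return 100.0 * failures / n_seeds, float(np.mean(max_errs))


def ols_oracle_max_diff(n_designs: int = 100, seed: int = 0) -> float:
    """Largest coefficient gap vs the normal-equations oracle."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_designs):
        n = int(rng.integers(20, 80))
        p = int(rng.integers(2, 8))
        x = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"f{j}" for j in range(p)])
        y = rng.normal(size=n)
        res = fit_property_regression(x, y)
        xz = (x - x.mean()) / x.std(ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        xd = np.column_stack([np.ones(n), xz.to_numpy()])
        oracle = np.linalg.solve(xd.T @ xd, xd.T @ yz)[1:]
        worst = max(worst, float(np.max(np.abs(
            res.betas["beta"].to_numpy() - oracle))))
    return worst


def type1_rate(n_seeds: int = 100, n: int = 100, p: int = 20,
               alpha: float = 0.05, seed: int = 0) -> float:
    """Fraction of null predictors flagged significant at alpha."""
    rng = np.random.default_rng(seed)
    flagged = total = 0
    for _ in range(n_seeds):
        x = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"f{j}" for j in range(p)])
        res = fit_property_regression(x, rng.normal(size=n))
        flagged += int((res.betas["p"] <= alpha).sum())
        total += p
    return flagged / total


def probe_localization_rate(n_scenes: int = 200, n_trials: int = 50,
                            d: int = 20, provider_profile: str = "event14",
                            seed: int = 0) -> float:
    """% of planted-signal trials whose argmax layer matches the source.

    Embeddings and per-layer PCA scores are computed once; each trial
    plants an outcome in a random layer's leading scores plus 10% noise.
    The probe dimension for this structural check is well below the scene
    count so per-layer fits are determined.
    """
    from .synthetic_data import toy_provider

    rng = np.random.default_rng(seed)
    scenes = [synth_scene(random_scene_spec(rng))[0] for _ in range(n_scenes)]
    provider = toy_provider(provider_profile, seed=int(rng.integers(2**31)))
    mats = ep.layer_feature_matrices(provider, scenes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = ep.layer_score_matrices(mats, d=d, seed=0)
    hits = 0
    for _ in range(n_trials):
        j = int(rng.integers(0, len(scores)))
        y = scores[j][:, :5] @ rng.normal(size=5)
        y = y + rng.normal(scale=0.1 * y.std(), size=y.shape)
        profile = ep.layerwise_regression_from_scores(scores, y)
        hits += int(np.argmax([lr.r2_adj for lr in profile.layers])) == j
    return 100.0 * hits / n_trials


DEPTH_CURVE_COEFFS = np.array([0.25, 2.0, -3.3, 1.2, 0.1])  # peak ~0.42


def depth_curve_peak_error(n_seeds: int = 100, sigma: float = 0.02,
                           n_layers: int = 17, seed: int = 0
                           ) -> tuple[float, float]:
    """(noiseless peak error, mean |peak error| under noise sigma)."""
    poly = np.polynomial.Polynomial(DEPTH_CURVE_COEFFS)
    grid = np.linspace(0, 1, 200001)
    true_peak = float(grid[np.argmax(poly(grid))])
    depths = np.linspace(0, 1, n_layers)

    def fit_with(noise_rng=None):
        r2s = poly(depths)
        if noise_rng is not None:
            r2s = r2s + noise_rng.normal(0, sigma, size=r2s.shape)
        layers = tuple(ep.LayerResult(i + 1, float(d), float(r), 0.01)
                       for i, (d, r) in enumerate(zip(depths, r2s)))
        fit = ep.fit_depth_curve(ep.LayerProfile("toy", "p", layers))
        return abs(fit.peak_depth - true_peak)

    noiseless = fit_with(None)
    rng = np.random.default_rng(seed)
    noisy = float(np.mean([fit_with(rng) for _ in range(n_seeds)]))
    return float(noiseless), noisy
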