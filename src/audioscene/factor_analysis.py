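"""Exploratory factor analysis: adequacy tests, parallel analysis, ML + oblique rotation.

The EFA stage answers "how many latent dimensions organize the scene
descriptors, and which variables load on which". Sampling adequacy is
checked with the Kaiser-Meyer-Olkin index (correlations vs anti-image
partial correlations) and Bartlett's sphericity test; the factor count
comes from parallel analysis (observed correlation-matrix eigenvalues
against a quantile of eigenvalues simulated from independent normal data
of the same shape); extraction is maximum likelihood with an oblique
rotation (oblimin by default, geomin exposed), and reported loadings are
conventionally blanked below |.40|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.factor import Factor


class SingularCorrelationError(ValueError):
    pass


@dataclass(frozen=True)
class EFAResult:
    loadings: pd.DataFrame          # variables x factors pattern matrix
    factor_corr: np.ndarray         # factors x factors
    variance_share: np.ndarray      # per-factor proportion of total variance
    total_variance: float
    n_factors: int
    rotation: str
    kmo: float
    bartlett: tuple[float, int, float]
    heywood: bool = False


@dataclass(frozen=True)
class ParallelAnalysisResult:
    observed_eigs: np.ndarray
    sim_quantiles: np.ndarray
    suggested_n: int


def _corr(data: np.ndarray) -> np.ndarray:
    r = np.corrcoef(np.asarray(data, dtype=np.float64), rowvar=False)
    if not np.all(np.isfinite(r)):
        raise SingularCorrelationError(
            "correlation matrix has undefined entries (constant column?)")
    return r


def kmo(data: np.ndarray) -> float:
    """Overall Kaiser-Meyer-Olkin sampling-adequacy index.

    KMO = sum r^2 / (sum r^2 + sum q^2) over off-diagonal cells, where q
    are the anti-image partial correlations from the inverse correlation
    matrix.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.shape[1] < 3:
        raise ValueError("KMO needs at least 3 variables")
    r = _corr(data)
    eigs = np.linalg.eigvalsh(r)
    if eigs.min() < 1e-10 * eigs.max():
        raise SingularCorrelationError("correlation matrix is singular")
    rinv = np.linalg.inv(r)
    d = np.sqrt(np.outer(np.diag(rinv), np.diag(rinv)))
    partial = -rinv / d
    off = ~np.eye(r.shape[0], dtype=bool)
    r2 = np.sum(r[off] ** 2)
    q2 = np.sum(partial[off] ** 2)
    return float(r2 / (r2 + q2))


def bartlett_sphericity(data: np.ndarray) -> tuple[float, int, float]:
    """Bartlett's test of sphericity: chi2, df = p(p-1)/2, p-value."""
    data = np.asarray(data, dtype=np.float64)
    n, p = data.shape
    if n <= p:
        raise ValueError("Bartlett's test needs more observations than variables")
    r = _corr(data)
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise SingularCorrelationError("correlation matrix not positive definite")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    p_value = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), p_value


def simulate_pa_quantiles(n_obs: int, n_var: int, n_sims: int = 1000,
                          quantile: float = 0.95,
                          seed: int | None = None) -> np.ndarray:
    """Rank-wise eigenvalue quantiles from independent standard-normal data.

    Expensive relative to the comparison itself, so callers scoring many
    datasets of identical shape can compute this once and pass it to
    :func:`parallel_analysis`.
    """
    rng = np.random.default_rng(seed)
    eigs = np.empty((n_sims, n_var))
    for s in range(n_sims):
        x = rng.standard_normal((n_obs, n_var))
        eigs[s] = np.sort(np.linalg.eigvalsh(np.corrcoef(x, rowvar=False)))[::-1]
    return np.quantile(eigs, quantile, axis=0)


def parallel_analysis(data: np.ndarray, n_sims: int = 1000,
                      quantile: float = 0.95, seed: int | None = None,
                      sim_quantiles: np.ndarray | None = None
                      ) -> ParallelAnalysisResult:
    """Factor-count suggestion by comparing observed vs simulated eigenvalues.

    Observed eigenvalues are principal-component eigenvalues of the
    correlation matrix; the suggested count is the length of the leading
    run of observed eigenvalues exceeding the simulated quantile at the
    same rank.
    """
    data = np.asarray(data, dtype=np.float64)
    observed = np.sort(np.linalg.eigvalsh(_corr(data)))[::-1]
    if sim_quantiles is None:
        sim_quantiles = simulate_pa_quantiles(data.shape[0], data.shape[1],
                                              n_sims, quantile, seed)
    exceeds = observed > sim_quantiles
    suggested = int(np.argmin(exceeds)) if not exceeds.all() else int(exceeds.size)
    return ParallelAnalysisResult(observed_eigs=observed,
                                  sim_quantiles=np.asarray(sim_quantiles),
                                  suggested_n=suggested)


def _canonicalize_signs(loadings: np.ndarray, phi: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Flip factor signs so each factor's largest-|loading| entry is positive."""
    flips = np.ones(loadings.shape[1])
    for j in range(loadings.shape[1]):
        k = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[k, j] < 0:
            flips[j] = -1.0
    l_out = loadings * flips[None, :]
    phi_out = phi * np.outer(flips, flips)
    return l_out, phi_out


def fit_efa(data: np.ndarray | pd.DataFrame, n_factors: int,
            rotation: str = "oblimin") -> EFAResult:
    """Maximum-likelihood EFA with oblique rotation.

    Variance shares use structure-weighted sums of squares: with pattern
    P and factor correlation Phi, the per-factor share is
    diag(P' P Phi) / n_variables, which sums to the mean communality.
    Heywood cases (communality >= 1) are clamped at 0.999 with a warning.
    """
    if isinstance(data, pd.DataFrame):
        names = list(data.columns)
        x = data.to_numpy(dtype=np.float64)
    else:
        x = np.asarray(data, dtype=np.float64)
        names = [f"v{i}" for i in range(x.shape[1])]
    if n_factors < 1 or n_factors > x.shape[1]:
        raise ValueError("inadmissible number of factors")
    kmo_val = kmo(x) if x.shape[1] >= 3 else float("nan")
    bart = bartlett_sphericity(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = Factor(x, n_factor=n_factors, method="ml")
        try:
            res = model.fit()
        except Exception as exc:
            raise RuntimeError(f"ML factor extraction failed to converge: {exc}") from exc
    heywood = False
    if np.any(res.uniqueness < 1e-3):
        heywood = True
        warnings.warn("Heywood case: communality clamped at 0.999", stacklevel=2)
    if n_factors > 1:
        res.rotate(rotation)
        pattern = np.asarray(res.loadings)
        t = np.asarray(res.rotation_matrix)
        phi = t.T @ t
    else:
        pattern = np.asarray(res.loadings)
        phi = np.ones((1, 1))
    pattern, phi = _canonicalize_signs(pattern, phi)
    communalities = np.sum((pattern @ phi) * pattern, axis=1)
    communalities = np.minimum(communalities, 0.999)
    shares = np.diag(pattern.T @ pattern @ phi) / x.shape[1]
    # order factors by explained variance, descending
    order = np.argsort(shares)[::-1]
    pattern = pattern[:, order]
    phi = phi[np.ix_(order, order)]
    shares = shares[order]
    loadings = pd.DataFrame(pattern, index=names,
                            columns=[f"F{j + 1}" for j in range(n_factors)])
    return EFAResult(loadings=loadings, factor_corr=phi,
                     variance_share=shares, total_variance=float(shares.sum()),
                     n_factors=n_factors, rotation=rotation, kmo=kmo_val,
                     bartlett=bart, heywood=heywood)


def loading_table(r: EFAResult, threshold: float = 0.40
                  ) -> tuple[pd.DataFrame, list[str]]:
    """Loadings with |value| < threshold blanked, ordered for display.

    Variables are sorted by their dominant factor, then by loading
    magnitude within it. Factors with no surviving loading are flagged.
    """
    vals = r.loadings.to_numpy()
    shown = np.where(np.abs(vals) >= threshold, vals, np.nan)
    dominant = np.argmax(np.abs(vals), axis=1)
    strength = np.max(np.abs(vals), axis=1)
    order = np.lexsort((-strength, dominant))
    table = pd.DataFrame(shown[order], index=r.loadings.index[order],
                         columns=r.loadings.columns)
    flags = [str(c) for c in table.columns if table[c].isna().all()]
    return table, flags


def align_loadings(estimated: np.ndarray, target: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align estimated factors to a target by congruence-maximizing permutation.

    Greedy column matching with sign flips; returns (aligned, perm, signs).
    Intended for simulation-recovery checks where factor order and sign
    are arbitrary.
    """
    est = np.asarray(estimated, dtype=np.float64)
    tgt = np.asarray(target, dtype=np.float64)
    k = tgt.shape[1]
    congruence = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            num = est[:, i] @ tgt[:, j]
            den = np.linalg.norm(est[:, i]) * np.linalg.norm(tgt[:, j])
            congruence[i, j] = num / den if den > 0 else 0.0
    perm = np.full(k, -1)
    signs = np.ones(k)
    free_rows = set(range(k))
    free_cols = set(range(k))
    for _ in range(k):
        i, j = max(((i, j) for i in free_rows for j in free_cols),
                   key=lambda ij: abs(congruence[ij[0], ij[1]]))
        perm[j] = i
        signs[j] = 1.0 if congruence[i, j] >= 0 else -1.0
        free_rows.discard(i)
        free_cols.discard(j)
    aligned = est[:, perm] * signs[None, :]
    return aligned, perm, signs
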