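"""Acoustic-feature regressions onto mean global-property ratings.

One ordinary-least-squares model per property: predictors and outcome
are z-scored so coefficients are standardized betas; the model is
summarized by R^2, adjusted R^2 (1 - (1 - R^2)(n - 1)/(n - p - 1)), the
full-model F test, and per-coefficient two-sided t tests. Known
near-duplicate predictors (e.g. overall vs pause-corrected RMS) are
retained deliberately; a variance-inflation report is emitted through
the warning list instead of dropping columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


class RankDeficientDesignError(ValueError):
    pass


@dataclass(frozen=True)
class RegressionResult:
    r2: float
    r2_adj: float
    f_value: float
    df1: int
    df2: int
    p_value: float
    betas: pd.DataFrame          # columns: beta, p
    warnings: tuple[str, ...] = ()


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R^2 penalizing the predictor count."""
    if n <= p + 1:
        raise ValueError("adjusted R^2 requires n > p + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    return (x - x.mean(axis=0)) / sd


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    """Name columns involved in exact rank deficiency via QR pivoting."""
    _, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    return [names[i] for i in range(len(names)) if diag[i] <= tol]


def fit_property_regression(features: pd.DataFrame, ratings: np.ndarray | pd.Series,
                            vif_threshold: float = 10.0) -> RegressionResult:
    """OLS of z-scored property means on the z-scored feature roster."""
    x_raw = features.to_numpy(dtype=np.float64)
    y_raw = np.asarray(ratings, dtype=np.float64)
    n, p = x_raw.shape
    if y_raw.shape[0] != n:
        raise ValueError("features and ratings must cover the same scenes")
    if n <= p + 1:
        raise ValueError(f"need more scenes ({n}) than predictors + 1 ({p + 1})")
    names = list(features.columns)
    constant = [names[j] for j in range(p) if x_raw[:, j].std() == 0]
    if constant:
        raise RankDeficientDesignError(f"zero-variance predictors: {constant}")
    xz = _zscore(x_raw)
    if np.linalg.matrix_rank(xz) < p:
        raise RankDeficientDesignError(
            f"collinear predictors: {_collinear_columns(xz, names)}")
    yz = _zscore(y_raw.reshape(-1, 1)).ravel()
    model = sm.OLS(yz, sm.add_constant(xz)).fit()
    warn: list[str] = []
    # VIF warning channel for near-duplicates kept in the roster
    corr = np.corrcoef(xz, rowvar=False)
    try:
        vifs = np.diag(np.linalg.inv(corr))
        high = [f"{names[j]} (VIF={vifs[j]:.1f})"
                for j in range(p) if vifs[j] > vif_threshold]
        if high:
            warn.append("high variance inflation: " + ", ".join(high))
    except np.linalg.LinAlgError:
        warn.append("VIF undefined: correlation matrix singular")
    betas = pd.DataFrame({"beta": model.params[1:], "p": model.pvalues[1:]},
                         index=names)
    return RegressionResult(
        r2=float(model.rsquared),
        r2_adj=float(adjusted_r2(model.rsquared, n, p)),
        f_value=float(model.fvalue), df1=p, df2=n - p - 1,
        p_value=float(model.f_pvalue), betas=betas, warnings=tuple(warn))


def usable_predictors(features: pd.DataFrame) -> pd.DataFrame:
    """Drop zero-variance and exactly collinear columns (keeping the first).

    Screening for small or degenerate designs; the study-scale roster is
    expected to pass through unchanged.
    """
    keep = [c for c in features.columns if features[c].std() > 0]
    out: list[str] = []
    for c in keep:
        cand = features[out + [c]].to_numpy(dtype=np.float64)
        cand = (cand - cand.mean(0)) / cand.std(0)
        if np.linalg.matrix_rank(cand) == len(out) + 1:
            out.append(c)
    return features[out]


def significant_predictors(r: RegressionResult, alpha: float = 0.05
                           ) -> pd.DataFrame:
    """Predictors with coefficient p <= alpha, plus a model summary row."""
    rows = [{"term": "<model>", "beta": np.nan, "p": r.p_value, "r2": r.r2,
             "r2_adj": r.r2_adj}]
    sig = r.betas[r.betas["p"] <= alpha]
    for name, row in sig.iterrows():
        rows.append({"term": name, "beta": row["beta"], "p": row["p"],
                     "r2": np.nan, "r2_adj": np.nan})
    return pd.DataFrame(rows)


def fit_all_properties(features: pd.DataFrame, property_means: pd.DataFrame,
                       alpha: float = 0.05
                       ) -> dict[str, RegressionResult]:
    """One regression per global property column."""
    return {prop: fit_property_regression(features, property_means[prop])
            for prop in property_means.columns}
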