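"""Rater-panel statistics: reliability, correlations, and accuracy scoring.

Inter-rater reliability uses the intraclass correlation from a two-way
random-effects ANOVA, average-measures, consistency form:

    ICC(C,k) = (MS_R - MS_E) / MS_R,   F = MS_R / MS_E,
    df1 = n - 1,  df2 = (n - 1)(k - 1)

with scenes as rows/targets and raters as columns. The consistency
definition discards rater main effects, so adding a constant to any
rater's column leaves the coefficient unchanged.

Accuracy scoring mirrors the judged-property conventions: temperature in
seven 15 °F bins from 15 to 126 °F, season over seven categories, and a
dichotomized outdoor/indoor scale with chance levels 100/7 % and 50 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

SEASON_CATEGORIES = (
    "Winter", "Between Winter and Spring", "Spring",
    "Between Spring and Summer", "Summer", "Between Summer and Fall", "Fall",
)
# note: the rating scale as administered has no "Between Fall and Winter" option

TEMPERATURE_BIN_START = 15
TEMPERATURE_BIN_STEP = 16   # bin starts: 15, 31, 47, 63, 79, 95, 111
TEMPERATURE_BIN_WIDTH = 15  # each bin spans start..start+15 inclusive
N_TEMPERATURE_BINS = 7


@dataclass(frozen=True)
class RatingMatrix:
    """Raters x scenes integer Likert grid (1-7) for one global property."""

    ratings: np.ndarray
    property_name: str
    scene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        r = np.asarray(self.ratings)
        if r.ndim != 2 or r.shape[0] < 2 or r.shape[1] < 2:
            raise ValueError("ratings must be a raters x scenes grid, >= 2 each")
        if not np.all((r >= 1) & (r <= 7)) or not np.all(r == np.round(r)):
            raise ValueError("ratings must be integers in 1..7 with no missing cells")
        object.__setattr__(self, "ratings", r.astype(np.int64))
        ids = self.scene_ids or tuple(f"scene{j:04d}" for j in range(r.shape[1]))
        if len(ids) != r.shape[1]:
            raise ValueError("scene_ids length must match the scene axis")
        object.__setattr__(self, "scene_ids", tuple(ids))

    @property
    def n_raters(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_scenes(self) -> int:
        return self.ratings.shape[1]

    def scene_means(self) -> np.ndarray:
        return self.ratings.mean(axis=0)


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    f_value: float
    df1: int
    df2: int
    p_value: float


@dataclass(frozen=True)
class SceneTruth:
    scene_id: str
    indoor_outdoor: str      # "indoor" | "outdoor"
    season: str              # one of SEASON_CATEGORIES
    temperature_f: float


class DegenerateRatingsError(ValueError):
    pass


def icc_2k(m: RatingMatrix, alpha: float = 0.05) -> ICCResult:
    """Two-way, consistency, average-measures intraclass correlation.

    Rows of the ANOVA are scenes (targets), columns are raters. The 95%
    confidence interval follows the F-quantile construction for the
    consistency/average-measures coefficient.
    """
    x = m.ratings.astype(np.float64).T  # scenes x raters
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    df1 = n - 1
    df2 = (n - 1) * (k - 1)
    ms_r = ss_rows / df1
    ms_e = ss_err / df2
    if ms_r <= 0:
        raise DegenerateRatingsError(
            "zero between-scene variance; ICC is undefined")
    icc = (ms_r - ms_e) / ms_r
    f_value = ms_r / ms_e if ms_e > 0 else np.inf
    p_value = float(stats.f.sf(f_value, df1, df2)) if np.isfinite(f_value) else 0.0
    fu = stats.f.ppf(1 - alpha / 2, df1, df2)
    fl = stats.f.ppf(1 - alpha / 2, df2, df1)
    ci_low = 1.0 - fu / f_value if np.isfinite(f_value) else 1.0
    ci_high = 1.0 - 1.0 / (f_value * fl) if np.isfinite(f_value) else 1.0
    return ICCResult(icc=float(icc), ci_low=float(ci_low), ci_high=float(ci_high),
                     f_value=float(f_value), df1=df1, df2=df2, p_value=p_value)


def property_correlations(means: pd.DataFrame
                          ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Pearson correlation matrix of per-scene property means with p-values.

    Returns (r, p, flags); zero-variance columns yield NaN entries for
    their pairs and a flag naming the column.
    """
    if means.shape[0] < 3:
        raise ValueError("need at least 3 scenes for correlations")
    cols = list(means.columns)
    p_count = len(cols)
    r = np.eye(p_count)
    p = np.zeros((p_count, p_count))
    flags = [c for c in cols if np.std(means[c].to_numpy()) == 0]
    for i in range(p_count):
        for j in range(i + 1, p_count):
            if cols[i] in flags or cols[j] in flags:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(means[cols[i]], means[cols[j]])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols), flags)


def bin_temperature(t: float) -> int:
    """Map a Fahrenheit temperature to its 15-degree bin (1..7).

    Bin edges: 15-30, 31-46, 47-62, 63-78, 79-94, 95-110, 111-126 °F.
    """
    if not (TEMPERATURE_BIN_START <= t <= 126):
        raise ValueError(f"temperature {t} °F outside the binnable range 15-126")
    b = int((t - TEMPERATURE_BIN_START) // TEMPERATURE_BIN_STEP) + 1
    return min(b, N_TEMPERATURE_BINS)


def chance_level(scheme: str) -> float:
    """Chance percent-correct for a response scheme (100 / #categories)."""
    categories = {"temperature": N_TEMPERATURE_BINS,
                  "season": len(SEASON_CATEGORIES),
                  "indoor_outdoor": 2}
    if scheme not in categories:
        raise ValueError(f"unknown scoring scheme {scheme!r}")
    return 100.0 / categories[scheme]


def _truth_map(truth: list[SceneTruth]) -> dict[str, SceneTruth]:
    return {t.scene_id: t for t in truth}


def percent_correct(m: RatingMatrix, truth: list[SceneTruth], scheme: str,
                    midpoint_policy: str = "exclude") -> dict[str, object]:
    """Per-rater and mean percent-correct against scene metadata.

    temperature: the 1-7 rating is compared with the true temperature
    bin. season: the rating indexes the seven season categories.
    indoor_outdoor: ratings 1-3 count as outdoor, 5-7 as indoor; the
    midpoint 4 is excluded by default (policies: exclude | nearest-low |
    nearest-high).
    """
    tmap = _truth_map(truth)
    missing = [sid for sid in m.scene_ids if sid not in tmap]
    if missing:
        raise ValueError(f"missing metadata for scenes: {missing[:5]}")
    ratings = m.ratings
    if scheme == "temperature":
        target = np.array([bin_temperature(tmap[sid].temperature_f)
                           for sid in m.scene_ids])
        correct = ratings == target[None, :]
        counted = np.ones_like(ratings, dtype=bool)
    elif scheme == "season":
        season_idx = {name: i + 1 for i, name in enumerate(SEASON_CATEGORIES)}
        target = np.array([season_idx[tmap[sid].season] for sid in m.scene_ids])
        correct = ratings == target[None, :]
        counted = np.ones_like(ratings, dtype=bool)
    elif scheme == "indoor_outdoor":
        target_indoor = np.array([tmap[sid].indoor_outdoor == "indoor"
                                  for sid in m.scene_ids])
        judged_indoor = ratings >= 5
        counted = np.ones_like(ratings, dtype=bool)
        if midpoint_policy == "exclude":
            counted = ratings != 4
        elif midpoint_policy == "nearest-low":
            judged_indoor = ratings > 4
        elif midpoint_policy == "nearest-high":
            judged_indoor = ratings >= 4
        else:
            raise ValueError(f"unknown midpoint policy {midpoint_policy!r}")
        correct = judged_indoor == target_indoor[None, :]
    else:
        raise ValueError(f"unknown scoring scheme {scheme!r}")
    counts = counted.sum(axis=1)
    with np.errstate(invalid="ignore"):
        per_rater = np.where(counts > 0,
                             100.0 * (correct & counted).sum(axis=1) / counts,
                             np.nan)
    return {"per_rater": per_rater,
            "mean": float(np.nanmean(per_rater)),
            "chance": chance_level(scheme)}


# ---------------------------------------------------------------------------
# long-format CSV ingestion

def ratings_from_long_csv(path: str | Path) -> dict[str, RatingMatrix]:
    """Read long-format ratings (rater_id, scene_id, property, rating)."""
    df = pd.read_csv(path)
    required = {"rater_id", "scene_id", "property", "rating"}
    if not required.issubset(df.columns):
        raise ValueError(f"ratings CSV must have columns {sorted(required)}")
    out: dict[str, RatingMatrix] = {}
    for prop, grp in df.groupby("property"):
        wide = grp.pivot(index="rater_id", columns="scene_id", values="rating")
        if wide.isna().any().any():
            raise ValueError(f"property {prop!r} has missing rater x scene cells")
        out[str(prop)] = RatingMatrix(ratings=wide.to_numpy(),
                                      property_name=str(prop),
                                      scene_ids=tuple(map(str, wide.columns)))
    return out


def metadata_from_csv(path: str | Path) -> list[SceneTruth]:
    """Read a scene-metadata table (scene_id, indoor_outdoor, season, temperature_f)."""
    df = pd.read_csv(path)
    return [SceneTruth(scene_id=str(r.scene_id),
                       indoor_outdoor=str(r.indoor_outdoor),
                       season=str(r.season),
                       temperature_f=float(r.temperature_f))
            for r in df.itertuples()]
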