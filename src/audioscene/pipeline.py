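"""Stage orchestration and report assembly.

Wires the stages together over documented file formats only
(WAV/CSV/JSON): acoustic features -> rating statistics -> EFA ->
acoustic-to-property regressions -> embedding probe -> report. Each
stage is callable on its own; ``run_all_synthetic`` runs the complete
pipeline on generated study conditions for a given seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import embedding_probe as ep
from . import factor_analysis as fa
from . import rating_stats as rs
from . import regression_mapping as rm
from .config import PipelineConfig
from .feature_table import DEFAULT_ROSTER, EXTENDED_ROSTER, feature_table, \
    feature_table_from_dir
from .synthetic_data import ALL_PROPERTIES, PROVIDER_REGISTRY, PanelSpec, \
    SceneSpec, Tone, random_scene_spec, synth_metadata, synth_panel, synth_scene

logger = logging.getLogger("audioscene")

REPORT_SECTIONS = ("features", "icc", "correlations", "accuracy", "efa",
                   "regressions", "probe")


def _roster(config: PipelineConfig) -> tuple[str, ...]:
    return EXTENDED_ROSTER if config.features.roster == "extended" else DEFAULT_ROSTER


def run_features(scene_dir: str | Path, config: PipelineConfig) -> pd.DataFrame:
    """Feature table for every readable WAV in ``scene_dir``."""
    return feature_table_from_dir(scene_dir, _roster(config))


def run_ratings(panels: dict[str, rs.RatingMatrix],
                truth: list[rs.SceneTruth] | None,
                config: PipelineConfig) -> dict:
    """ICC per property, property inter-correlations, accuracy vs metadata."""
    icc = {}
    for prop, matrix in panels.items():
        r = rs.icc_2k(matrix)
        icc[prop] = {"icc": r.icc, "ci_low": r.ci_low, "ci_high": r.ci_high,
                     "f_value": r.f_value, "df1": r.df1, "df2": r.df2,
                     "p_value": r.p_value}
    means = pd.DataFrame({prop: m.scene_means() for prop, m in panels.items()})
    corr, pvals, flags = rs.property_correlations(means)
    accuracy = {}
    if truth is not None:
        schemes = {"Temperature": "temperature", "Season": "season",
                   "Outdoor vs. Indoor": "indoor_outdoor"}
        for prop, scheme in schemes.items():
            if prop in panels:
                pc = rs.percent_correct(panels[prop], truth, scheme,
                                        config.ratings.midpoint_policy)
                accuracy[prop] = {"mean": pc["mean"], "chance": pc["chance"]}
    return {"icc": icc, "property_means": means,
            "correlations": corr, "correlation_p": pvals,
            "correlation_flags": flags, "accuracy": accuracy}


def run_efa(data: pd.DataFrame, config: PipelineConfig,
            seed: int | None = None) -> dict:
    """Parallel analysis then ML + oblique EFA at the suggested factor count."""
    x = data.to_numpy(dtype=np.float64)
    pa = fa.parallel_analysis(x, n_sims=config.efa.pa_sims,
                              quantile=config.efa.pa_quantile, seed=seed)
    n_factors = max(pa.suggested_n, 1)
    result = fa.fit_efa(data, n_factors, rotation=config.efa.rotation)
    table, empty = fa.loading_table(result, config.efa.threshold)
    return {"kmo": result.kmo, "bartlett": result.bartlett,
            "suggested_n": pa.suggested_n, "n_factors": n_factors,
            "variance_share": result.variance_share.tolist(),
            "total_variance": result.total_variance,
            "loadings": result.loadings, "loading_table": table,
            "empty_factors": empty, "rotation": result.rotation}


def run_regressions(features: pd.DataFrame, means: pd.DataFrame,
                    config: PipelineConfig) -> dict:
    """One acoustic-to-property regression per global property."""
    out = {}
    for prop in means.columns:
        res = rm.fit_property_regression(features, means[prop])
        out[prop] = {"r2": res.r2, "r2_adj": res.r2_adj, "f": res.f_value,
                     "df1": res.df1, "df2": res.df2, "p": res.p_value,
                     "significant": rm.significant_predictors(
                         res, config.regress.alpha),
                     "warnings": list(res.warnings)}
    return out


def run_probe(provider_name: str, scenes, means: pd.DataFrame,
              config: PipelineConfig, seed: int = 0) -> dict:
    """Layer-wise and aggregate probe of one provider for every property."""
    provider = PROVIDER_REGISTRY[provider_name](seed=seed)
    mats = ep.layer_feature_matrices(provider, scenes)
    scores = ep.layer_score_matrices(mats, config.embed.d, seed)
    out: dict = {"provider": provider_name, "n_layers": provider.n_layers,
                 "properties": {}}
    for prop in means.columns:
        y = means[prop].to_numpy()
        profile = ep.layerwise_regression_from_scores(
            scores, y, model_name=provider.name, property_name=prop)
        agg = ep.aggregate_regression_from_scores(scores, y, config.embed.d, seed)
        entry = {
            "layers": [{"layer": lr.layer_index, "depth": lr.relative_depth,
                        "r2_adj": lr.r2_adj, "p": lr.p_value}
                       for lr in profile.layers],
            "aggregate_r2_adj": agg,
        }
        try:
            curve = ep.fit_depth_curve(profile, config.embed.alpha)
            entry["peak_depth"] = curve.peak_depth
        except ValueError as exc:
            entry["peak_depth"] = None
            logger.warning("depth curve for %s: %s", prop, exc)
        out["properties"][prop] = entry
    return out


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_report(stage_outputs: dict) -> dict:
    """Assemble the final report; absent stages are marked as such."""
    report = {}
    for section in REPORT_SECTIONS:
        if section in stage_outputs and stage_outputs[section] is not None:
            report[section] = _jsonable(stage_outputs[section])
        else:
            report[section] = {"status": "absent"}
    return report


def validate_report(report: dict) -> None:
    """Structural check of a report object (all sections present, JSON-able)."""
    missing = [s for s in REPORT_SECTIONS if s not in report]
    if missing:
        raise ValueError(f"report missing sections: {missing}")
    json.dumps(report)  # must round-trip


def run_all_synthetic(seed: int, config: PipelineConfig | None = None,
                      n_scenes: int = 60, n_probe_scenes: int | None = None
                      ) -> dict:
    """Full pipeline on synthetic study conditions.

    Problem sizes default below the full study scale so the complete run
    stays interactive; every stage uses its study-default parameters.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    # scenes + acoustic features
    specs = [random_scene_spec(rng) for _ in range(n_scenes)]
    scenes = [synth_scene(s)[0] for s in specs]
    feats = feature_table(scenes, _roster(config))
    # rater panel + metadata
    panels, _, true_means = synth_panel(PanelSpec(
        n_scenes=n_scenes, seed=int(rng.integers(2**31))))
    truth = synth_metadata(n_scenes, seed=int(rng.integers(2**31)))
    ratings_out = run_ratings(panels, truth, config)
    # EFA on the property means
    efa_out = run_efa(ratings_out["property_means"], config,
                      seed=int(rng.integers(2**31)))
    # regressions: features predict property means (small-n guard: screen
    # degenerate predictors and cap the count below n - 2)
    means = ratings_out["property_means"]
    usable = rm.usable_predictors(feats)
    max_predictors = max(n_scenes - 3, 1)
    feat_cols = list(usable.columns)[:max_predictors]
    reg_out = run_regressions(usable[feat_cols], means.set_axis(feats.index),
                              config)
    # embedding probe on the same scenes
    probe_out = run_probe(config.embed.provider, scenes,
                          means.set_axis(feats.index), config,
                          seed=int(rng.integers(2**31)))
    report = run_report({
        "features": feats, "icc": ratings_out["icc"],
        "correlations": ratings_out["correlations"],
        "accuracy": ratings_out["accuracy"], "efa": {
            k: v for k, v in efa_out.items() if k != "loadings"},
        "regressions": {p: {k: v for k, v in d.items() if k != "significant"}
                        for p, d in reg_out.items()},
        "probe": probe_out,
    })
    validate_report(report)
    return report
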