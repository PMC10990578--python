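"""Validated pipeline configuration.

All stage parameters surface here with their conventional defaults
(10 ms ramps, 4 dB / 20 ms burst rule, 16 ms correlogram and 50 ms
centroid windows, PCA dimension 136, |.40| loading threshold, alpha
0.05). Unknown keys are rejected so typos fail loudly before any stage
runs.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AudioConfig(_Strict):
    target_rms: float = Field(0.05, gt=0)
    ramp_ms: float = Field(10.0, ge=0)


class FeaturesConfig(_Strict):
    roster: str = "default"  # default | extended


class EFAConfig(_Strict):
    rotation: str = "oblimin"
    pa_sims: int = Field(1000, ge=10)
    pa_quantile: float = Field(0.95, gt=0, lt=1)
    threshold: float = Field(0.40, ge=0)


class RegressConfig(_Strict):
    alpha: float = Field(0.05, gt=0, lt=1)


class EmbedConfig(_Strict):
    d: int = Field(136, ge=1)
    alpha: float = Field(0.05, gt=0, lt=1)
    provider: str = "toy-event14"


class RatingsConfig(_Strict):
    midpoint_policy: str = "exclude"  # exclude | nearest-low | nearest-high


class PipelineConfig(_Strict):
    seed: int = 0
    audio: AudioConfig = Field(default_factory=AudioConfig)
    features: FeaturesConfig = Field(default_factory=FeaturesConfig)
    ratings: RatingsConfig = Field(default_factory=RatingsConfig)
    efa: EFAConfig = Field(default_factory=EFAConfig)
    regress: RegressConfig = Field(default_factory=RegressConfig)
    embed: EmbedConfig = Field(default_factory=EmbedConfig)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a YAML config; defaults when ``path`` is None."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)
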