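"""Pipeline configuration schema, presets, and config hashing.

A config fully determines pipeline behaviour: which detector and which
stage-specific segmenter run, the model frame sizes, the detection
confidence floor, the auto-acceptance tolerance, and the mask
post-processing rules.  Three presets mirror the study designs this
package evaluates:

* ``baseline`` — single segmenter for both stages, box-only prompts;
* ``final`` — stage-specific segmenters, early-stage background points;
* ``inverted`` — the stage-inversion ablation: early images are routed
  to the late-stage segmenter *and* late-stage prompt configuration,
  and vice versa.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigurationError

__all__ = ["PostprocessConfig", "PipelineConfig", "load_config", "PRESETS"]


class PostprocessConfig(BaseModel):
    model_config = {"frozen": True}

    largest_component: bool = True
    fill_holes: bool = False
    min_component_px: int = Field(default=16, ge=0)


class PipelineConfig(BaseModel):
    """Everything the measurement chain needs, minus backend instances."""

    model_config = {"frozen": True}

    config_id: str = "custom"
    detector_id: str = "oracle"
    segmenter_id_early: str = "oracle"
    segmenter_id_late: str = "oracle"
    detect_resize: int = Field(default=640, gt=0)
    segment_resize: int = Field(default=1024, gt=0)
    confidence_min: float = Field(default=0.25, ge=0.0, le=1.0)
    aar_tolerance: float = Field(default=0.05, gt=0.0)
    #: route early detections to the late branch and vice versa (ablation)
    invert_routing: bool = False
    #: attach the four edge-midpoint background points on the early branch
    early_background_points: bool = True
    postprocess: PostprocessConfig = PostprocessConfig()
    #: passed through to backend factories (e.g. jitter_px, delta_px)
    detector_options: dict = Field(default_factory=dict)
    segmenter_options: dict = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if not self.segmenter_id_early or not self.segmenter_id_late:
            raise ConfigurationError("exactly one segmenter id per stage is required")
        return self

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True,
                          separators=(",", ":"))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:12]


PRESETS: dict[str, PipelineConfig] = {
    "baseline": PipelineConfig(
        config_id="baseline",
        segmenter_id_early="segmenter",
        segmenter_id_late="segmenter",
        early_background_points=False,
    ),
    "final": PipelineConfig(
        config_id="final",
        segmenter_id_early="segmenter-early",
        segmenter_id_late="segmenter-late",
    ),
    "inverted": PipelineConfig(
        config_id="inverted",
        segmenter_id_early="segmenter-early",
        segmenter_id_late="segmenter-late",
        invert_routing=True,
    ),
}


def load_config(source: "str | Path | dict") -> PipelineConfig:
    """Load a config from a preset name, a YAML/JSON file, or a dict."""
    if isinstance(source, dict):
        return PipelineConfig.model_validate(source)
    if isinstance(source, (str, Path)):
        name = str(source)
        if name in PRESETS:
            return PRESETS[name]
        path = Path(source)
        if not path.is_file():
            raise ConfigurationError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text())
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        return PipelineConfig.model_validate(data)
    raise ConfigurationError(f"cannot load config from {type(source)}")
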