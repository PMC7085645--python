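"""Structured-text (YAML) pipeline configuration.

One file holds everything a deployment tunes: the ROI rectangle, the
feature-raster resolution and its target network profile, the class scheme,
and the prefilter area thresholds.  Every field is optional and falls back
to the package defaults; the resolution/network pairing is validated at
load time (the raster may never exceed the network's input-vector width).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .labeler import SCHEMES, LabelerConfig
from .preprocess import DEFAULT_ROI, PrefilterConfig, ResolutionProfile, RoiSpec

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class PipelineConfig:
    roi: RoiSpec = DEFAULT_ROI
    resolution: ResolutionProfile = ResolutionProfile(16, 16, "cm1k")
    scheme: str = "simple"
    prefilter: PrefilterConfig = field(default_factory=PrefilterConfig)

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; one of {SCHEMES}")

    def labeler_config(self) -> LabelerConfig:
        return LabelerConfig(roi=self.roi, prefilter=self.prefilter)


def load_config(path: str | Path) -> PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    kwargs: dict = {}
    if "roi" in doc:
        kwargs["roi"] = RoiSpec(**doc["roi"])
    if "resolution" in doc:
        kwargs["resolution"] = ResolutionProfile(**doc["resolution"])
    if "scheme" in doc:
        kwargs["scheme"] = doc["scheme"]
    if "prefilter" in doc:
        kwargs["prefilter"] = PrefilterConfig(**doc["prefilter"])
    return PipelineConfig(**kwargs)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    doc = {
        "roi": {"x0": cfg.roi.x0, "y0": cfg.roi.y0,
                "x1": cfg.roi.x1, "y1": cfg.roi.y1},
        "resolution": {"out_w": cfg.resolution.out_w,
                       "out_h": cfg.resolution.out_h,
                       "network": cfg.resolution.network},
        "scheme": cfg.scheme,
        "prefilter": {
            "threshold": cfg.prefilter.threshold,
            "min_contrast": cfg.prefilter.min_contrast,
            "component_min_area": cfg.prefilter.component_min_area,
            "small_max_area": cfg.prefilter.small_max_area,
            "min_olive_area": cfg.prefilter.min_olive_area,
            "max_olive_area": cfg.prefilter.max_olive_area,
            "double_min_components": cfg.prefilter.double_min_components,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
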