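"""YAML configuration: model, training, and guidance sections.

Example::

    model:
      crop_size: 96
      context: aspp
      seed: 0
    train:
      base_lr: 0.01
      epochs: 50
    guidance:
      radius: 40.0
      weight_radius: 120.0
    fusion:
      threshold: 0.0
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .guidance import GuidanceConfig
from .networks import ModelConfig
from .training import TrainConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    model: ModelConfig
    train: TrainConfig
    guidance: GuidanceConfig
    fusion_threshold: float = 0.0


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        for section, kv in overrides.items():
            raw.setdefault(section, {}).update(kv)
    model_kw = dict(raw.get("model", {}))
    if "widths" in model_kw:
        model_kw["widths"] = tuple(model_kw["widths"])
    mc = ModelConfig(**model_kw)
    tc = TrainConfig(**raw.get("train", {}))
    g_kw = raw.get("guidance", None)
    gc = GuidanceConfig(**g_kw) if g_kw else GuidanceConfig().scaled_for(mc.crop_size)
    thr = float(raw.get("fusion", {}).get("threshold", 0.0))
    return PipelineConfig(model=mc, train=tc, guidance=gc, fusion_threshold=thr)
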