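"""YAML configuration loading for pipeline and enhancement parameters."""

from __future__ import annotations

import dataclasses

import yaml

from .enhancement import EnhancementParams
from .pipeline import MontageSpec, PipelineConfig


def _build(cls, mapping: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - valid
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return cls(**mapping)


def load_enhancement_params(path) -> EnhancementParams:
    """Read :class:`EnhancementParams` from a YAML mapping (defaults fill gaps)."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh) or {}
    return _build(EnhancementParams, mapping)


def load_pipeline_config(path) -> PipelineConfig:
    """Read :class:`PipelineConfig` from YAML; an optional ``montage`` mapping
    may override the electrode groups."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh) or {}
    if "montage" in mapping:
        m = mapping.pop("montage")
        mapping["montage"] = MontageSpec(
            left_channels=tuple(m.get("left_channels", MontageSpec().left_channels)),
            right_channels=tuple(m.get("right_channels", MontageSpec().right_channels)),
            reference=m.get("reference", "Cz"))
    return _build(PipelineConfig, mapping)
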