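"""YAML configuration: one file with preprocess / coarse / refine / train
sections mapped onto the corresponding dataclasses."""

from __future__ import annotations

from dataclasses import asdict, fields
from pathlib import Path

import yaml

from .networks import CoarseNetConfig, RefineNetConfig, TrainConfig
from .phantom import PhantomSpec
from .preprocess import PreprocessConfig

__all__ = ["load_config", "save_config", "SECTIONS"]

SECTIONS = {
    "preprocess": PreprocessConfig,
    "coarse": CoarseNetConfig,
    "refine": RefineNetConfig,
    "train": TrainConfig,
    "phantom": PhantomSpec,
}


def _build(cls, values: dict):
    valid = {f.name for f in fields(cls)}
    unknown = set(values) - valid
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    coerced = {}
    for f in fields(cls):
        if f.name in values:
            v = values[f.name]
            coerced[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load a config file into ``{section: dataclass}``; missing sections
    get defaults."""
    doc = {}
    if path is not None:
        doc = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        for sec, vals in overrides.items():
            doc.setdefault(sec, {}).update(vals)
    return {name: _build(cls, doc.get(name, {})) for name, cls in SECTIONS.items()}


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_listify(v) for v in obj]
    return obj


def save_config(configs: dict, path) -> None:
    doc = {name: _listify(asdict(cfg)) for name, cfg in configs.items()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
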