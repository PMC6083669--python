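"""YAML <-> dataclass plumbing for scene, degradation and evaluation configs."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from .align import SimilarityTransform
from .degrade import DegradeSpec
from .distance import DistanceClassScheme
from .evaluate import EvalConfig
from .scene import SceneParams

__all__ = [
    "load_yaml",
    "scene_params_from_dict",
    "degrade_spec_from_dict",
    "eval_config_from_dict",
]


def load_yaml(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def _build(cls, data: dict, name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown {name} keys: {sorted(unknown)}")
    return cls(**data)


def scene_params_from_dict(data: dict) -> SceneParams:
    params = _build(SceneParams, data, "scene parameter")
    params.validate()
    return params


def degrade_spec_from_dict(data: dict) -> DegradeSpec:
    data = dict(data)
    if data.get("pose_perturbation") is not None:
        data["pose_perturbation"] = SimilarityTransform.from_dict(data["pose_perturbation"])
    if data.get("floating_region") is not None:
        data["floating_region"] = np.asarray(data["floating_region"], dtype=np.float64)
    spec = _build(DegradeSpec, data, "degrade spec")
    spec.validate()
    return spec


def eval_config_from_dict(data: dict) -> EvalConfig:
    data = dict(data)
    if "scheme" in data and data["scheme"] is not None:
        data["scheme"] = DistanceClassScheme(**data["scheme"])
    return _build(EvalConfig, data, "evaluation config")
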