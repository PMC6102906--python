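"""Run configuration: a single YAML file with one section per subsystem,
flat CLI overrides, and a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .emg_validator import ValidatorConfig
from .perception import CameraModel
from .planner import ArmWorkspace
from .synth_signals import EMGModel, ERPModel


@dataclass
class DecoderConfig:
    band: tuple[float, float] = (2.0, 25.0)
    decim: int = 25
    p_enter: float = 0.10
    p_remove: float = 0.15
    max_features: int = 60
    n_sequences: int = 3
    n_calibration_trials: int = 60  # five sets of 12 trials


@dataclass
class RunConfig:
    seed: int = 0
    scenario: str = "A"
    sessions: int = 1
    output_dir: str = "out"
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    validator: ValidatorConfig = field(default_factory=ValidatorConfig)
    camera: CameraModel = field(default_factory=CameraModel)
    workspace: ArmWorkspace = field(default_factory=ArmWorkspace)
    erp: ERPModel = field(default_factory=ERPModel)
    emg: EMGModel = field(default_factory=EMGModel)


_SECTIONS = {
    "decoder": DecoderConfig,
    "validator": ValidatorConfig,
    "camera": CameraModel,
    "workspace": ArmWorkspace,
    "erp": ERPModel,
    "emg": EMGModel,
}


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    kwargs = {}
    for key, val in data.items():
        if key in _SECTIONS:
            if not isinstance(val, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            val = {k: (tuple(v) if isinstance(v, list) else v)
                   for k, v in val.items()}
            kwargs[key] = _SECTIONS[key](**val)
        else:
            kwargs[key] = val
    return RunConfig(**kwargs)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(_jsonable(cfg), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_manifest(cfg: RunConfig, path) -> dict:
    """Record everything needed to reproduce a run bit-for-bit."""
    from . import __version__
    manifest = {
        "config": _jsonable(cfg),
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "versions": {"neurochair": __version__, "numpy": np.__version__},
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
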