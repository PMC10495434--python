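"""JSON/YAML (de)serialization of model configurations and traces."""

from __future__ import annotations

import dataclasses
import json
import math

import numpy as np
import yaml

from .core_models import (
    LNOUConfig,
    NegMomentumConfig,
    OUConfig,
    SimulationTrace,
    SizeDependentFit,
    StimulationModifier,
    WalledGaussianConfig,
)

__all__ = [
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "dump_config",
    "write_trace",
]

_MODEL_TYPES = {
    "gaussian-walled": WalledGaussianConfig,
    "ou": OUConfig,
    "negmom": NegMomentumConfig,
    "lnou": LNOUConfig,
    "fit": SizeDependentFit,
    "stimulation": StimulationModifier,
}
_TYPE_NAMES = {cls: name for name, cls in _MODEL_TYPES.items()}


def _encode(value):
    if isinstance(value, SizeDependentFit):
        return config_to_dict(value)
    if isinstance(value, float) and math.isinf(value):
        return "inf"
    if isinstance(value, tuple):
        return list(value)
    return value


def config_to_dict(cfg) -> dict:
    """Dataclass config -> plain dict with a ``type`` discriminator."""
    if type(cfg) not in _TYPE_NAMES:
        raise TypeError(f"not a serializable config: {type(cfg).__name__}")
    out = {"type": _TYPE_NAMES[type(cfg)]}
    for f in dataclasses.fields(cfg):
        if f.name == "stderr":
            continue
        out[f.name] = _encode(getattr(cfg, f.name))
    return out


def config_from_dict(data: dict):
    """Inverse of :func:`config_to_dict`."""
    data = dict(data)
    type_name = data.pop("type")
    cls = _MODEL_TYPES[type_name]
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if isinstance(value, dict) and value.get("type") == "fit":
            value = config_from_dict(value)
        elif value == "inf":
            value = math.inf
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


def load_config(path):
    """Load a model config from a YAML or JSON file."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


def dump_config(cfg, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def write_trace(trace: SimulationTrace, path) -> None:
    """Wide CSV (row = spine, column = step) plus a sidecar JSON.

    The sidecar ``<path>.json`` records seed, step labels, floor hits and
    the generating config so the trace is reproducible.
    """
    n_steps = trace.n_steps
    header = "spine_id," + ",".join(f"step_{i}" for i in range(n_steps + 1))
    ids = np.arange(trace.n_spines)[:, None]
    np.savetxt(
        path,
        np.column_stack([ids, trace.sizes]),
        delimiter=",",
        header=header,
        comments="",
        fmt=["%d"] + ["%.17g"] * (n_steps + 1),
    )
    cfg = trace.config
    if isinstance(cfg, tuple):
        cfg_json = [config_to_dict(c) for c in cfg]
    else:
        cfg_json = config_to_dict(cfg)
    sidecar = {
        "seed": trace.seed,
        "step_labels": list(trace.step_labels),
        "floor_hits": trace.floor_hits,
        "config": cfg_json,
    }
    with open(str(path) + ".json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2)
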