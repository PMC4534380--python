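"""YAML configuration files for model parameters and stimulus schedules.

The config dialect is flat YAML with three optional top-level sections:
``hopfield`` (attractor constants), ``model`` (decision-maker parameters)
and ``stimulus`` (noise level, schedule, frame length). Unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import fields

import numpy as np
import yaml

from .attractor import HopfieldParams
from .stimulus import StimulusSpec
from .ukf import BattmConfig

__all__ = ["load_config", "save_config"]


def _build(cls, data: dict, **extra):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data, **extra)


def load_config(path) -> tuple[BattmConfig, StimulusSpec | None]:
    """Read a YAML config; returns (model config, stimulus spec or None)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    hop = _build(HopfieldParams, raw.get("hopfield", {}))
    model = dict(raw.get("model", {}))
    if "M" in model:
        model["M"] = np.asarray(model["M"], dtype=float)
    cfg = _build(BattmConfig, model, hopfield=hop)
    spec = None
    if "stimulus" in raw:
        stim = dict(raw["stimulus"])
        if "schedule" in stim:
            stim["schedule"] = tuple(
                (int(a), float(d)) for a, d in stim["schedule"]
            )
        if "prototypes" in stim:
            stim["prototypes"] = np.asarray(stim["prototypes"], dtype=float)
        else:
            stim["prototypes"] = cfg.M
        stim.setdefault("dt_ms", cfg.dt_ms)
        spec = _build(StimulusSpec, stim)
    return cfg, spec


def save_config(path, cfg: BattmConfig, spec: StimulusSpec | None = None) -> None:
    """Write a config readable by :func:`load_config`."""
    hop = {f.name: getattr(cfg.hopfield, f.name) for f in fields(HopfieldParams)}
    model = {
        "M": cfg.M.tolist(),
        "r": cfg.r,
        "q": cfg.q,
        "p0": cfg.p0,
        "dt_ms": cfg.dt_ms,
        "lambda_thresh": cfg.lambda_thresh,
        "T0_ms": cfg.T0_ms,
        "timeout_ms": cfg.timeout_ms,
        "out_slope": cfg.out_slope,
        "out_centre": cfg.out_centre,
        "time_unit_ms": cfg.time_unit_ms,
    }
    doc = {"hopfield": hop, "model": model}
    if spec is not None:
        doc["stimulus"] = {
            "noise_level": spec.noise_level,
            "schedule": [list(seg) for seg in spec.schedule],
            "frame_ms": spec.frame_ms,
            "dt_ms": spec.dt_ms,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
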