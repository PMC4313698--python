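"""YAML configuration loading/saving for reproducible runs.

A run config is a nested mapping with optional sections ``network``,
``hebb``, ``protocol`` and ``stimuli``; anything omitted falls back to
the package defaults, so an empty file is a valid config.  Every run
writes a manifest (config echo, seed, version, parameter hash) next to
its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .model import (AreaParams, HandRegion, LateralKernelParams, MSUnitParams,
                    NetworkParams, StimulusSpec, SynapseParams)
from .plasticity import HebbParams, TrainingProtocol


def _build(cls, data: Mapping[str, Any] | None, **nested):
    data = dict(data or {})
    for key, builder in nested.items():
        data[key] = builder(data.get(key))
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def _area(defaults: AreaParams):
    def build(data):
        if data is None:
            return defaults
        data = dict(data)
        if "lateral" in data and isinstance(data["lateral"], Mapping):
            data["lateral"] = LateralKernelParams(**data["lateral"])
        return dataclasses.replace(defaults, **data)
    return build


def network_params_from_dict(data: Mapping[str, Any] | None) -> NetworkParams:
    base = NetworkParams()
    if not data:
        return base
    data = dict(data)
    out: dict[str, Any] = {}
    if "tactile" in data:
        out["tactile"] = _area(base.tactile)(data.pop("tactile"))
    if "auditory" in data:
        out["auditory"] = _area(base.auditory)(data.pop("auditory"))
    if "ms_unit" in data:
        out["ms_unit"] = dataclasses.replace(base.ms_unit, **data.pop("ms_unit"))
    if "synapses" in data:
        out["synapses"] = dataclasses.replace(base.synapses, **data.pop("synapses"))
    if "hand" in data:
        h = data.pop("hand")
        out["hand"] = HandRegion(tuple(h["x_interval"]), tuple(h["y_interval"]))
    for key in ("dt", "steady_tol"):
        if key in data:
            out[key] = data.pop(key)
    if data:
        raise ValueError(f"unknown network keys: {sorted(data)}")
    return dataclasses.replace(base, **out)


def hebb_params_from_dict(data: Mapping[str, Any] | None) -> HebbParams:
    return dataclasses.replace(HebbParams(), **(data or {}))


def protocol_from_dict(data: Mapping[str, Any] | None,
                       soa_mode: str | None = None) -> TrainingProtocol:
    data = dict(data or {})
    for key in ("tactile_stim", "auditory_stim"):
        if key in data and isinstance(data[key], Mapping):
            stim = dict(data[key])
            stim["center"] = tuple(stim.get("center", (100.0, 5.0)))
            data[key] = StimulusSpec(**stim)
    if "soa_range" in data:
        data["soa_range"] = tuple(data["soa_range"])
    if soa_mode is not None:
        data["soa_mode"] = soa_mode
    return dataclasses.replace(TrainingProtocol(), **data)


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Read a YAML config file (missing file is an error; None -> defaults)."""
    if path is None:
        return {}
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return data


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def params_hash(*objects: Any) -> str:
    payload = json.dumps([_jsonable(o) for o in objects], sort_keys=True,
                         default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(out_dir: str | Path, seed: int | None,
                   config: Mapping[str, Any], **extra: Any) -> Path:
    """Record the run's provenance next to its outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "ppsnet",
        "version": __version__,
        "seed": seed,
        "config": _jsonable(dict(config)),
        "params_hash": params_hash(dict(config), seed),
        **_jsonable(extra),
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
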