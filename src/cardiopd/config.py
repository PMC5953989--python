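"""Run configuration: YAML/JSON with sections
{dataset, pk_parameters, estimation, simulation, seeds}."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from .exposure import DEFAULT_TRASTUZUMAB_PK, TrastuzumabPKParams

SECTIONS = ("dataset", "pk_parameters", "estimation", "simulation", "seeds")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


def load_config(path) -> dict[str, Any]:
    """Load and minimally validate a run configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    cfg = (json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)) or {}
    if not isinstance(cfg, Mapping):
        raise ConfigError("config root must be a mapping")
    unknown = set(cfg) - set(SECTIONS)
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    out = {s: dict(cfg.get(s) or {}) for s in SECTIONS}
    seeds = out["seeds"]
    for k, v in seeds.items():
        if not isinstance(v, int):
            raise ConfigError(f"seed {k!r} must be an integer")
    return out


def pk_from_config(cfg: Mapping[str, Any]) -> TrastuzumabPKParams:
    """Trastuzumab PK block {CL, V1, Q, V2} (L/day, L); defaults are the
    package's literature-typical values when the block is absent."""
    block = cfg.get("pk_parameters") or {}
    if not block:
        return DEFAULT_TRASTUZUMAB_PK
    try:
        return TrastuzumabPKParams(
            clearance=float(block["CL"]),
            central_volume=float(block["V1"]),
            intercompartmental_clearance=float(block["Q"]),
            peripheral_volume=float(block["V2"]),
        )
    except KeyError as exc:
        raise ConfigError(
            f"pk_parameters block incomplete: missing {exc}") from exc


def config_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
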