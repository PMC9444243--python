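"""Project configuration: a YAML key/value tree with schema validation,
dotted-path overrides, and run manifests."""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "paths": {
        "raw": "raw",
        "rois": "rois",
        "models": "models",
        "results": "results",
    },
    "acquisition": {
        "frame_interval_min": 5.0,
        "pixel_size_um": 0.325,
        "channels": ["brightfield", "gfp"],
        "z_planes": 3,
    },
    "rules": {
        "arrest_hours": 10.0,
        "pp_mode": "none",
        "pairing_tolerance_frames": 2,
        "threshold_grid": [0.3, 0.5, 0.7, 0.9],
        "skipped_small_fallback": True,
    },
    "simulate": {
        "n_cells": 20,
        "t_frames": 150,
        "death_hazard": 0.05,
        "sep_hazard": 0.08,
        "render": True,
        "image_size": 48,
        "noise_sigma": 0.03,
    },
    "train": {
        "frame_cnn": {"epochs": 20, "learning_rate": 3e-3, "batch_size": 64},
        "lstm": {"hidden": 32, "epochs": 30, "learning_rate": 1e-2, "batch_size": 16},
        "sep": {"hidden": 32, "epochs": 30, "learning_rate": 1e-2, "batch_size": 16},
        "segmenter": {"width": 8, "epochs": 12, "learning_rate": 3e-3, "batch_size": 8},
    },
    "seed": 0,
}


class ConfigError(ValueError):
    pass


def _validate(tree: dict, schema: dict, path: str = "") -> None:
    for key, value in tree.items():
        here = f"{path}.{key}" if path else key
        if key not in schema:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(schema[key], dict) and not isinstance(value, dict):
            raise ConfigError(f"config key {here} must be a mapping")
        if isinstance(schema[key], dict):
            _validate(value, schema[key], here)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults merged with an optional YAML file; unknown keys rejected."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        _validate(user, DEFAULTS)
        cfg = _merge(cfg, user)
    if cfg["acquisition"]["frame_interval_min"] <= 0:
        raise ConfigError("acquisition.frame_interval_min must be > 0")
    window = cfg["rules"]["arrest_hours"] * 60 / cfg["acquisition"]["frame_interval_min"]
    if abs(window - round(window)) > 1e-9:
        raise ConfigError("rules.arrest_hours must be an integer number of frames")
    if not isinstance(cfg["seed"], int):
        raise ConfigError("seed must be an integer")
    return cfg


def apply_override(cfg: dict, dotted: str, raw_value: str) -> None:
    """Set ``a.b.c=value`` in place, parsing the value as YAML."""
    keys = dotted.split(".")
    node = cfg
    schema = DEFAULTS
    for key in keys[:-1]:
        if not isinstance(schema, dict) or key not in schema:
            raise ConfigError(f"unknown config key: {dotted}")
        node = node.setdefault(key, {})
        schema = schema[key]
    if not isinstance(schema, dict) or keys[-1] not in schema:
        raise ConfigError(f"unknown config key: {dotted}")
    node[keys[-1]] = yaml.safe_load(raw_value)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def write_manifest(out_dir: str | Path, subcommand: str, cfg: dict, inputs: list[str]) -> None:
    import divtrap

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subcommand": subcommand,
        "config_hash": config_hash(cfg),
        "config": cfg,
        "inputs": sorted(inputs),
        "seed": cfg.get("seed"),
        "version": divtrap.__version__,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
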