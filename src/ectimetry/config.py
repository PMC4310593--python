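"""Run configuration: one YAML/JSON file drives every subcommand.

The configuration mirrors the acquisition geometry of the study
(512×512 px at 0.625 μm/px lateral, 1 μm axial) as defaults, carries a
schema version, and rejects unknown keys by name. CLI flags override
config values; no stochastic run proceeds without a resolvable seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .errors import ConfigError
from .phantom import (
    BoundaryModel,
    CohortSpec,
    HISTOLOGY_COHORT_SPECS,
    IMAGING_COHORT_SPECS,
    NoiseModel,
    PhantomParams,
)

SCHEMA_VERSION = 1

DEFAULTS: dict = {
    "schema_version": SCHEMA_VERSION,
    "seed": None,
    "phantom": {
        "fov_width": 320.0, "fov_depth": 320.0,
        "px_lateral": 0.625, "px_axial": 1.0,
        "keratin_thickness": 10.0, "bit_depth": 8,
        "render_nuclei": False, "texture_sd": 0.25,
        "noise": {"gaussian_sd": 2.0, "poisson_gain": 0.25},
    },
    "boundary": {
        "baseline_depth": 150.0, "sine_amplitude": 0.0,
        "sine_period": 80.0, "bumps": [], "roughness_sd": 0.0,
    },
    "trace": {
        "sigma": 2.0, "low": 0.4, "high": 0.8,
        "smooth_halfwidth": 2, "eps": 0.01, "max_bridge_px": 20,
    },
    "cohort": {"modality": "imaging", "specs": None},
    "stats": {"criterion": "youden"},
}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, value in user.items():
        if key not in defaults:
            raise ConfigError(f"unknown config key: {path}{key}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, f"{path}{key}.")
        else:
            out[key] = value
    for key, value in defaults.items():
        out.setdefault(key, json.loads(json.dumps(value)))  # deep copy
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load and validate a config file, applying CLI overrides on top."""
    user: dict = {}
    if path is not None:
        text = Path(path).read_text()
        user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"{path}: config must be a mapping")
    cfg = _merge(DEFAULTS, user)
    if cfg["schema_version"] != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {cfg['schema_version']}")
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        section = cfg
        *parents, leaf = key.split(".")
        for p in parents:
            section = section[p]
        if leaf not in section:
            raise ConfigError(f"unknown config key: {key}")
        section[leaf] = value
    return cfg


def require_seed(cfg: dict) -> int:
    if cfg.get("seed") is None:
        raise ConfigError("no seed: set 'seed' in the config or pass --seed")
    return int(cfg["seed"])


def phantom_params(cfg: dict, seed: int) -> PhantomParams:
    p = cfg["phantom"]
    return PhantomParams(
        fov_width=p["fov_width"], fov_depth=p["fov_depth"],
        px_lateral=p["px_lateral"], px_axial=p["px_axial"],
        keratin_thickness=p["keratin_thickness"],
        noise=NoiseModel(**p["noise"]), texture_sd=p["texture_sd"],
        render_nuclei=p["render_nuclei"], bit_depth=p["bit_depth"],
        rng_seed=seed,
    )


def boundary_model(cfg: dict) -> BoundaryModel:
    b = cfg["boundary"]
    return BoundaryModel(
        baseline_depth=b["baseline_depth"], sine_amplitude=b["sine_amplitude"],
        sine_period=b["sine_period"],
        bumps=tuple(tuple(x) for x in b["bumps"]),
        roughness_sd=b["roughness_sd"],
    )


def cohort_specs(cfg: dict) -> tuple[CohortSpec, ...]:
    c = cfg["cohort"]
    if c["specs"]:
        return tuple(CohortSpec(**spec) for spec in c["specs"])
    if c["modality"] == "imaging":
        return IMAGING_COHORT_SPECS
    if c["modality"] == "histology":
        return HISTOLOGY_COHORT_SPECS
    raise ConfigError(f"unknown cohort modality {c['modality']!r}")
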