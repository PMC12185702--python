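"""Pipeline configuration: nested defaults, strict validation, YAML round-trip.

A configuration is a nested dict mirroring ``DEFAULTS``; unknown keys are
rejected up front so typos cannot silently fall back to defaults.  One global
seed is fanned out to per-stage child seeds through a stable hash.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "synthetic": {
        "n_features": {"rna": 2000, "protein": 800, "phospho": 600},
        "n_factors": 4,
        "effect_size": 2.0,
        "n_signature": 30,
    },
    "preprocess": {
        "min_observed_frac": 0.5,
        "tail_shift": 1.8,
        "tail_sd_scale": 0.3,
        "lfc_thresh": 1.0,
        "p_thresh": 0.05,
    },
    "tfa": {
        "k_max": 15,
        "k_min": 2,
        "lam": 0.01,
        "tol": 1e-6,
        "max_iter": 500,
        "z_thresh": 1.0,
        "exclusion_z": 0.0,
    },
    "enrichment": {
        "alpha": 0.75,
        "n_perm": 1000,
        "ksea_p_cut": 0.05,
        "ksea_m_min": 5,
        "min_effect": 0.5,
    },
    "network": {
        "min_refs": 3,
        "edge_min_refs": 3,
        "null_B": 100,
    },
    "survival": {
        "n_patients": 160,
        "true_hazard_ratio": 0.25,
        "censoring_rate": 0.3,
        "min_group_frac": 0.1,
    },
    "drugs": {
        "delta": 0.2,
        "replicate_noise_sd": 0.05,
    },
}


def _check_keys(cfg: dict, ref: dict, path: str = "") -> None:
    for key, val in cfg.items():
        if key not in ref:
            raise KeyError(f"unknown config key: {path}{key}")
        if isinstance(ref[key], dict) and not isinstance(val, dict):
            raise TypeError(f"config key {path}{key} must be a mapping")
        if isinstance(ref[key], dict):
            _check_keys(val, ref[key], f"{path}{key}.")


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def make_config(overrides: dict | None = None) -> dict:
    """Defaults merged with ``overrides``; unknown keys raise KeyError."""
    overrides = overrides or {}
    _check_keys(overrides, DEFAULTS)
    return _merge(DEFAULTS, overrides)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return make_config(yaml.safe_load(fh) or {})


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{int(seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
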