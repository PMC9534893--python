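"""Pipeline configuration: defaults, YAML loading, and hashing."""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

from .exceptions import ParameterError

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "gabamorph_run",
    "design": {
        "cultivars": ["Atabaki", "Rabab"],
        "gaba_levels_mM": [0.0, 10.0, 20.0, 40.0],
        "stress_levels": ["control", "drought", "salt", "combined"],
        "timepoints_days": [0.0, 14.0, 30.0, 45.0],
        "replicates": 4,
    },
    "generator": {},  # overrides for default_generator_params fields
    "images": {"n_leaves": 8, "px_per_cm": 40.0, "speckle_rate": 0.01, "hole_rate": 0.02},
    "encoding": {"one_hot": False},
    "split": {"train_frac": 0.8},
    "mlp": {"hidden_layers": [14, 12], "l2": 1e-4, "max_iter": 2000},
    "rbf": {"k": 25, "ridge": 1e-8},
    "sensitivity": {"mode": "retrain_without", "model": "mlp"},
    "nsga": {"pop_size": 100, "generations": 800, "crossover_prob": 0.8, "mutation_rate": 0.04},
    "morphometry": {"min_component_px": 20, "petiole_opening_radius": 4},
}


def _deep_update(base: dict, extra: dict) -> dict:
    for key, value in extra.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, optionally merged with a YAML file and a dict of
    overrides (in that order)."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ParameterError(f"config file {path} must contain a mapping")
        _deep_update(config, loaded)
    if overrides:
        _deep_update(config, overrides)
    return config


def config_hash(config: dict) -> str:
    """Short stable digest of a configuration, embedded in output
    headers.  The output directory is excluded: it locates the run but
    does not affect any computed value."""
    scrubbed = {k: v for k, v in config.items() if k != "output_dir"}
    canon = json.dumps(scrubbed, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
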