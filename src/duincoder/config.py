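"""Run configuration: nested YAML over documented defaults.

Unknown keys are rejected so typos fail loudly. The shipped ``default``
profile reproduces the reference experimental settings (10 s window, 7:2:1
split, contamination 0.01, K = 32, 2000 epochs, Adam lr 0.0004 with decay
0.95 per 50 epochs, cosine-annealing period 200, validation every 20
epochs); the ``smoke`` profile scales everything down for minute-scale runs.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "log_level": "INFO",
    "simulator": {
        "records_per_cell": 5,
        "duration_s": None,
    },
    "signals": {
        "window_seconds": 10.0,
        "frame_rate": 10.0,
        "split_ratio": [7, 2, 1],
        "stratify": False,
        "std_floor": None,
    },
    "model": {
        "variant": "R",
        "n_categories": 16,
        "latent_dim": 64,
        "hidden_cat": [512, 256],
        "hidden_en": [512, 256],
        "hidden_de": [256, 512],
        "gumbel_temperature": 1.0,
        "epochs": 2000,
        "lr0": 0.0004,
        "lr_decay": 0.95,
        "lr_step_epochs": 50,
        "anneal_period_epochs": 200,
        "val_interval_epochs": 20,
        "k_val": 32,
        "batch_size": 256,
        "max_train_windows": None,
        "max_val_windows": None,
    },
    "detector": {
        "contamination": 0.01,
        "n_trees": 100,
        "subsample_size": 256,
        "mode": "vector",
        "k_infer": 32,
    },
    "evaluation": {
        "threshold": 0.05,
    },
}


class ConfigError(ValueError):
    pass


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{here} must be a mapping")
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None,
                profile: str | None = None) -> dict:
    """Resolve a config: defaults <- shipped profile <- user YAML file."""
    cfg = copy.deepcopy(DEFAULTS)
    if profile is not None:
        ref = resources.files("duincoder").joinpath(f"configs/{profile}.yaml")
        if not ref.is_file():
            raise ConfigError(f"unknown config profile {profile!r}")
        cfg = _merge(cfg, yaml.safe_load(ref.read_text()) or {})
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _merge(cfg, user)
    return cfg
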