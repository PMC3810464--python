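"""Structured input/output: configs (TOML/JSON), profile CSVs, JSON reports."""

from __future__ import annotations

import json
import tomllib
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .params import ModelParams, SingleSexParams

__all__ = [
    "load_config",
    "save_config",
    "params_from_config",
    "save_profile_csv",
    "load_profile_csv",
    "save_json",
    "load_json",
]

PathLike = Union[str, Path]


def load_config(path: PathLike) -> dict:
    """Read a TOML or JSON configuration file (by extension)."""
    path = Path(path)
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    with open(path) as fh:
        return json.load(fh)


def save_config(cfg: dict, path: PathLike) -> None:
    """Write a configuration as JSON (the writable interchange format)."""
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")


def params_from_config(cfg: dict) -> ModelParams:
    """Build ModelParams from a config dict's 'model' section (or the dict itself)."""
    section = cfg.get("model", cfg)
    keys = ("r", "mu_f", "mu_m", "D_f", "D_m", "sigma")
    return ModelParams(**{k: section[k] for k in keys if k in section})


def single_sex_from_config(cfg: dict) -> SingleSexParams:
    section = cfg.get("model", cfg)
    keys = ("mu", "D", "sigma")
    return SingleSexParams(**{k: section[k] for k in keys if k in section})


def save_profile_csv(path: PathLike, x: np.ndarray, **columns: np.ndarray) -> None:
    """Write a density profile as CSV with an x column plus named density columns."""
    df = pd.DataFrame({"x": x, **columns})
    df.to_csv(path, index=False)


def load_profile_csv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def save_json(obj: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def load_json(path: PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")
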