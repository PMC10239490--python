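"""Configuration loading: model presets, muscle tables, contact/ACL parameters.

All angles are degrees in config files and radians internally; all other
quantities are SI.  Two model presets ship with the package:

``nominal_3d``
    The full skier: free pelvis, ball lumbar and hips, revolute knees and
    ankles (19 DOF), locked subtalar/mtp joints, arms welded to the trunk,
    94 Hill-type muscles, an 18-segment ski.

``reduced_planar``
    A sagittal-plane skier (planar pelvis + hip/knee/ankle per leg, 9 DOF)
    with a 16-muscle set, used for dynamic simulation and tracking at desk
    scale.
"""

from __future__ import annotations

import copy
import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

_DATA = resources.files("skiturn") / "_data"


def _data_path(name: str) -> Path:
    p = _DATA / name
    if not p.is_file():
        raise FileNotFoundError(f"no shipped config named {name!r}")
    return Path(str(p))


def load_yaml(path_or_preset: str | Path) -> dict:
    """Load a YAML config, resolving bare preset names against shipped data."""
    p = Path(path_or_preset)
    if not p.is_file():
        p = _data_path(f"{path_or_preset}.yaml")
    with open(p) as fh:
        return yaml.safe_load(fh)


def load_model_config(name_or_path: str | Path = "reduced_planar") -> dict:
    cfg = load_yaml(name_or_path)
    for key in ("segments", "joints"):
        if key not in cfg:
            raise ValueError(f"model config missing {key!r} section")
    return cfg


def load_muscle_table(name_or_path: str | Path) -> pd.DataFrame:
    """Read a muscle table (one row per muscle; see shipped CSVs for schema)."""
    p = Path(name_or_path)
    if not p.is_file():
        p = _data_path(f"{name_or_path}.csv")
    df = pd.read_csv(p)
    required = {"name", "f_max", "l_opt", "l_slack", "penn_opt", "tau_act", "tau_deact", "moment_arms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"muscle table missing columns: {sorted(missing)}")
    return df


def parse_moment_arms(entry: str) -> dict[str, list[float]]:
    """Parse ``"coord:c0,c1;coord2:c0"`` into {coord: ascending poly coeffs (m)}."""
    out: dict[str, list[float]] = {}
    if not isinstance(entry, str) or not entry.strip():
        return out
    for part in entry.split(";"):
        coord, _, coeffs = part.partition(":")
        out[coord.strip()] = [float(c) for c in coeffs.split(",")]
    return out


def load_acl_coefficients(name_or_path: str | Path = "acl_coefficients") -> dict:
    cfg = load_yaml(name_or_path)
    for key in ("sagittal_proportion", "frontal", "transverse", "patellar_tendon_angle"):
        if key not in cfg:
            raise ValueError(f"ACL coefficient file missing {key!r}")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config dict, for fixture manifests."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def with_overrides(cfg: dict, overrides: dict) -> dict:
    """Deep-merged copy of ``cfg`` with ``overrides`` applied."""
    out = copy.deepcopy(cfg)

    def merge(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    merge(out, overrides)
    return out


def deg2rad(x):
    return np.deg2rad(x)


def rad2deg(x):
    return np.rad2deg(x)
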