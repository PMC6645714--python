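"""Plain-text I/O: trial tables as commented CSV, parameter sets and
bounds as YAML key-value configs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .params import LuminanceParams
from .race_model import TRIAL_COLUMNS

__all__ = ["write_trial_table", "read_trial_table", "write_params_config",
           "read_params_config", "read_bounds_config", "config_hash",
           "write_table"]

REQUIRED_COLUMNS = TRIAL_COLUMNS[:10]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(meta: dict | None) -> list[str]:
    lines = [f"# antisaccade version: {__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}: {v}")
    return lines


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write any DataFrame as CSV with a commented provenance header."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def write_trial_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing required columns: {missing}")
    write_table(df, path, meta)


def read_trial_table(path) -> pd.DataFrame:
    """Read a trial-table CSV, skipping ``#`` header comments.

    Raises a schema error naming any missing required column.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: not a trial table; missing columns {missing}; "
            f"expected at least {REQUIRED_COLUMNS}")
    return df


def write_params_config(params_by_luminance: dict, path,
                        meta: dict | None = None) -> None:
    payload = {lum: p.to_dict() for lum, p in params_by_luminance.items()}
    path = Path(path)
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_params_config(path) -> dict:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: expected a mapping of luminance -> parameters")
    return {lum: LuminanceParams.from_dict(d) for lum, d in payload.items()}


def read_bounds_config(path) -> dict:
    """Bounds config: mapping parameter name -> [lo, hi] (or a single pinned
    value)."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    out = {}
    for name, v in payload.items():
        if isinstance(v, (int, float)):
            out[name] = (float(v), float(v))
        else:
            lo, hi = v
            out[name] = (float(lo), float(hi))
    return out
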