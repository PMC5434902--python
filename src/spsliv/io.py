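"""Serialization helpers: CSV tables, role-map configs, JSON fit output.

CSV dialect: comma-separated with a header row, ``.`` decimal, empty cell
or ``NA`` for missing.  Floats are written with 17 significant digits so
a written dataset re-reads to identical fits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError

__all__ = ["read_table", "write_table", "read_config", "write_json"]

FLOAT_FORMAT = "%.17g"
NA_VALUES = ["", "NA"]


def read_table(path) -> pd.DataFrame:
    """Read a CSV with header row; '' and 'NA' are missing markers."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(
        path, na_values=NA_VALUES, keep_default_na=False,
        float_precision="round_trip",
    )


def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT, na_rep="NA")


def read_config(path) -> dict:
    """Read a YAML or JSON configuration file into a dict."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            cfg = json.loads(text)
        else:
            cfg = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as err:
        raise ConfigError(f"malformed config file {path}: {err}") from err
    if not isinstance(cfg, Mapping):
        raise ConfigError(f"config file {path} must contain a mapping")
    return dict(cfg)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(payload: dict, path=None) -> str:
    """Serialize with sorted keys so identical runs are byte-identical."""
    text = json.dumps(payload, indent=2, sort_keys=True, default=_jsonable) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
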