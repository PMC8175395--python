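"""Typed CSV/JSON readers and writers shared by the pipeline stages.

Tables are plain UTF-8, dot-decimal CSV. A header mismatch or a column that
fails numeric parsing (e.g. a comma-decimal file) raises a SchemaError
listing the offending columns rather than silently misparsing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "EQUILIBRIUM_SCHEMA",
    "KINETICS_SCHEMA",
    "THERMO_SCHEMA",
    "DESIGN_SCHEMA",
    "read_table",
    "write_table",
    "write_json",
]

FLOAT_FORMAT = "%.6g"

EQUILIBRIUM_SCHEMA = ("ce_mg_L", "qe_mg_g")
KINETICS_SCHEMA = ("t_min", "qt_mg_g")
THERMO_SCHEMA = ("T_K", "bL_L_per_mg")
DESIGN_SCHEMA = ("pH", "contactTime", "initialConcentration", "dosage", "response")


class SchemaError(ValueError):
    """Raised when a table's header or column types do not match the schema."""


def read_table(path: str | Path, schema: Sequence[str]) -> pd.DataFrame:
    """Read a CSV whose header must contain exactly the schema's columns.

    Extra columns beyond the schema are permitted only if they parse as
    numeric too (design tables carry coded-level columns); missing or
    non-numeric schema columns raise :class:`SchemaError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing columns {missing}; found {list(df.columns)}"
        )
    bad = []
    for col in schema:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad.append(col)
    if bad:
        raise SchemaError(
            f"{path}: columns {bad} are not numeric "
            "(comma decimal separators are not supported)"
        )
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as dot-decimal CSV with 6-significant-digit floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else float(f"{f:.6g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_json(obj, path: str | Path) -> Path:
    """Write a report as JSON with sorted keys and %.6g float formatting.

    The fixed formatting plus per-stage seeds make repeated runs of the same
    configuration byte-identical.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")
    return path
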