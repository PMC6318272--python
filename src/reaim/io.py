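"""Tidy trial-table CSV round trip with schema validation."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import TRIAL_COLUMNS

__all__ = ["read_trials", "write_trials", "validate_trials"]

_BOOL_COLUMNS = ("on_time", "feedback", "is_catch")


class SchemaError(ValueError):
    pass


def validate_trials(table: pd.DataFrame) -> pd.DataFrame:
    """Check the declared column set and value ranges; returns the table."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    unknown = [c for c in table.columns if c not in TRIAL_COLUMNS]
    if missing or unknown:
        raise SchemaError(
            f"trial table schema mismatch: missing={missing} "
            f"unknown={unknown}")
    angles = table["hand_angle_deg"].to_numpy(dtype=float)
    bad = np.flatnonzero(~((angles > -180.0) & (angles <= 180.0)))
    if bad.size:
        raise SchemaError(
            "hand_angle_deg outside (-180, 180] at rows "
            f"{bad[:20].tolist()}")
    if (table["rt_ms"] < 0).any():
        rows = table.index[table["rt_ms"] < 0][:20].tolist()
        raise SchemaError(f"negative rt_ms at rows {rows}")
    return table


def write_trials(table: pd.DataFrame, path) -> None:
    validate_trials(table[TRIAL_COLUMNS])
    table.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def read_trials(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if table.empty and list(table.columns) == TRIAL_COLUMNS:
        for c in _BOOL_COLUMNS:
            table[c] = table[c].astype(bool)
        return table
    table = validate_trials(table)
    for c in _BOOL_COLUMNS:
        table[c] = table[c].astype(bool)
    return table
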