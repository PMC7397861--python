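"""Canonical on-disk formats: trial CSV, participants CSV, ground-truth JSON.

The trial CSV schema is frozen (version 1); readers reject unknown schemas
loudly so that analysis code can rely on column names and types.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

TRIAL_COLUMNS = [
    "participant_id", "block", "trial_in_block", "effort", "reward",
    "trial_type", "force_response", "force_error", "x_true", "x_target",
    "performance_error", "x_estimate", "estimation_error",
]

PARTICIPANT_COLUMNS = [
    "participant_id", "max_force_n", "ami_behavioral_activation",
    "ami_emotional_sensitivity", "ami_social_motivation", "ami_total",
]


def trials_to_frame(trials) -> pd.DataFrame:
    """Flatten a list of Trial objects into the canonical trial table."""
    rows = [{c: getattr(t, c) for c in TRIAL_COLUMNS} for t in trials]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def write_trials(df: pd.DataFrame, path) -> None:
    _check_columns(df, TRIAL_COLUMNS, "trial")
    df.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    _check_columns(df, TRIAL_COLUMNS, "trial")
    return df


def write_participants(df: pd.DataFrame, path) -> None:
    _check_columns(df, PARTICIPANT_COLUMNS, "participants")
    df.to_csv(path, index=False)


def read_participants(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    _check_columns(df, PARTICIPANT_COLUMNS, "participants")
    return df


def _check_columns(df: pd.DataFrame, expected: list[str], kind: str) -> None:
    if list(df.columns) != expected:
        raise ValueError(
            f"unrecognized {kind} schema: columns {list(df.columns)!r}; "
            f"expected exactly {expected!r}")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
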