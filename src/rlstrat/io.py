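"""Session-log and results I/O.

Session logs are UTF-8 CSV, one row per trial, header required, columns
``session_id, trial_index, odor_id, correct_side, choice, reward``,
0-based contiguous trial indices per session.  Parameter files map
parameter name -> value (JSON object or two-column CSV).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .trials import COLUMNS, TrialValidationError, validate_trials


def read_sessions(path: str | Path) -> pd.DataFrame:
    """Read and validate a session-log CSV; rows ordered by trial within session."""
    df = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError(f"{path}: missing column(s) {missing}")
    df = df[COLUMNS]
    validate_trials(df)
    return (
        df.sort_values(["session_id", "trial_index"], kind="stable").reset_index(drop=True)
    )


def write_sessions(df: pd.DataFrame, path: str | Path) -> None:
    validate_trials(df)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[COLUMNS].to_csv(path, index=False)


def read_params(path: str | Path) -> dict[str, float]:
    """Read a parameter file (JSON object or name,value CSV)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return {str(k): float(v) for k, v in data.items()}
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: parameter CSV needs name,value columns")
    name_col, value_col = df.columns[:2]
    return {str(r[name_col]): float(r[value_col]) for _, r in df.iterrows()}


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(x):
    try:
        return x.item()
    except AttributeError:
        return str(x)
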