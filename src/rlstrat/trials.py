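"""Trial-table schema and validation.

A session log is a :class:`pandas.DataFrame` with one row per trial and
columns ``session_id``, ``trial_index`` (0-based, contiguous within a
session), ``odor_id`` (stimulus identity), ``correct_side`` (``"L"``/``"R"``),
``choice`` (``"L"``/``"R"``), ``reward`` (0/1).  Reward is deterministic:
``reward == 1`` exactly when ``choice == correct_side``.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
import pandas as pd

COLUMNS = ["session_id", "trial_index", "odor_id", "correct_side", "choice", "reward"]
SIDES = ("L", "R")


class TrialValidationError(ValueError):
    """A trial table violates the session-log contract."""


def validate_trials(df: pd.DataFrame, single_session: bool = False) -> pd.DataFrame:
    """Validate a trial table against the session-log contract.

    Checks column presence, side labels, the deterministic-reward
    invariant and per-session 0-based contiguous trial indices.  Returns
    the validated frame (unchanged) so the call can be chained.

    Raises
    ------
    TrialValidationError
        Naming the offending column or row numbers.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError(f"missing required column(s): {missing}")
    if len(df) == 0:
        raise TrialValidationError("empty trial table")

    for col in ("correct_side", "choice"):
        bad = ~df[col].isin(SIDES)
        if bad.any():
            rows = df.index[bad].tolist()[:5]
            raise TrialValidationError(f"column {col!r} has values outside {SIDES} at rows {rows}")

    rew = df["reward"].to_numpy()
    if not np.isin(rew, (0, 1)).all():
        raise TrialValidationError("column 'reward' must be 0/1")

    expected = (df["choice"] == df["correct_side"]).astype(int).to_numpy()
    bad = rew != expected
    if bad.any():
        rows = df.index[np.nonzero(bad)[0]].tolist()[:5]
        raise TrialValidationError(
            f"reward inconsistent with choice vs correct_side at rows {rows} "
            "(reward must equal indicator(choice == correct_side))"
        )

    for sid, grp in df.groupby("session_id", sort=False):
        idx = np.sort(grp["trial_index"].to_numpy())
        if not np.array_equal(idx, np.arange(len(grp))):
            raise TrialValidationError(
                f"session {sid!r}: trial_index must be 0-based and contiguous"
            )

    if single_session and df["session_id"].nunique() > 1:
        raise TrialValidationError("expected a single session, got multiple session_id values")
    return df


def iter_sessions(df: pd.DataFrame) -> Iterator[tuple[object, pd.DataFrame]]:
    """Yield ``(session_id, session_frame)`` pairs ordered by trial_index."""
    for sid, grp in df.groupby("session_id", sort=False):
        yield sid, grp.sort_values("trial_index").reset_index(drop=True)


def session_arrays(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Encode a single ordered session as integer arrays for the likelihood core.

    Returns ``(odor_idx, choice_idx, reward, n_odors)`` where odors are
    coded by order of first appearance and choices as L=0, R=1.
    """
    df = df.sort_values("trial_index")
    odor_codes, _ = pd.factorize(df["odor_id"], sort=False)
    choice = (df["choice"] == "R").to_numpy(dtype=np.int64)
    reward = df["reward"].to_numpy(dtype=np.int64)
    return odor_codes.astype(np.int64), choice, reward, int(odor_codes.max()) + 1
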