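"""Behavioral summaries: learning curves and repeat/non-repeat splits.

Learning curves are binned by *presentations per stimulus* (default 25),
not raw trial index, so sessions with different set sizes are directly
comparable; the stimulus-averaged curve is the mean over odors per bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trials import validate_trials

BIN_SIZE = 25


class MetricsError(ValueError):
    pass


def learning_curve(records: pd.DataFrame, bin_size: int = BIN_SIZE) -> pd.DataFrame:
    """Per-odor and stimulus-averaged fraction correct per presentation bin.

    Returns a tidy frame with columns ``odor`` (odor id or ``"mean"``),
    ``bin`` (1-based), ``fraction_correct``, ``n`` and ``partial`` (True
    for a final bin with fewer than ``bin_size`` presentations; partial
    bins are excluded from the ``"mean"`` rows).
    """
    df = validate_trials(records, single_session=True).sort_values("trial_index")
    rows = []
    per_odor: dict = {}
    for odor, grp in df.groupby("odor_id", sort=False):
        rew = grp["reward"].to_numpy()
        for b in range(int(np.ceil(len(rew) / bin_size))):
            chunk = rew[b * bin_size : (b + 1) * bin_size]
            partial = len(chunk) < bin_size
            rows.append(
                {"odor": odor, "bin": b + 1, "fraction_correct": chunk.mean(),
                 "n": len(chunk), "partial": partial}
            )
            if not partial:
                per_odor.setdefault(b + 1, []).append(chunk.mean())
    n_odors = df["odor_id"].nunique()
    for b in sorted(per_odor):
        vals = per_odor[b]
        if len(vals) == n_odors:  # bin complete for every odor
            rows.append({"odor": "mean", "bin": b, "fraction_correct": float(np.mean(vals)),
                         "n": n_odors * bin_size, "partial": False})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RepeatSplit:
    """Accuracy on repeat vs non-repeat trials (classified from trial 2 on)."""

    repeat_accuracy: float
    nonrepeat_accuracy: float
    n_repeat: int
    n_nonrepeat: int
    flagged: bool = False  # single-trial session: nothing to classify


def repeat_split(records: pd.DataFrame) -> RepeatSplit:
    """Split accuracy by whether the stimulus repeats the previous trial's."""
    df = validate_trials(records, single_session=True).sort_values("trial_index")
    if len(df) < 2:
        return RepeatSplit(np.nan, np.nan, 0, 0, flagged=True)
    odor = df["odor_id"].to_numpy()
    rew = df["reward"].to_numpy()
    is_rep = odor[1:] == odor[:-1]
    correct = rew[1:]
    n_rep = int(is_rep.sum())
    n_non = int((~is_rep).sum())
    return RepeatSplit(
        repeat_accuracy=float(correct[is_rep].mean()) if n_rep else np.nan,
        nonrepeat_accuracy=float(correct[~is_rep].mean()) if n_non else np.nan,
        n_repeat=n_rep,
        n_nonrepeat=n_non,
    )


def fraction_correct(records: pd.DataFrame) -> float:
    """Overall session fraction correct."""
    df = validate_trials(records, single_session=True)
    return float(df["reward"].mean())


def session_metrics(sessions: pd.DataFrame, bin_size: int = BIN_SIZE) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Learning curves and repeat splits for every session in a table."""
    curves, splits = [], []
    for sid in dict.fromkeys(sessions["session_id"]):
        sdf = sessions[sessions["session_id"] == sid]
        c = learning_curve(sdf, bin_size)
        c.insert(0, "session_id", sid)
        curves.append(c)
        s = repeat_split(sdf)
        splits.append({"session_id": sid, "repeat_accuracy": s.repeat_accuracy,
                       "nonrepeat_accuracy": s.nonrepeat_accuracy,
                       "n_repeat": s.n_repeat, "n_nonrepeat": s.n_nonrepeat})
    return pd.concat(curves, ignore_index=True), pd.DataFrame(splits)
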