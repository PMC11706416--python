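"""Synthetic odor 2AFC task schedules and simulated sessions.

Emulates the structure of an operant two-alternative forced-choice
session: 2 or 4 concurrently learned odors, each presented a fixed
number of times (default 200) in a pseudorandom interleaved order with
controlled gaps between repeats of the same stimulus, deterministic
reward for the correct side, and choice behavior generated by the RL +
one-back-strategy model family of :mod:`rlstrat.models`.

Schedules are built by shuffling within consecutive blocks that contain
each odor exactly once, which yields a unimodal same-stimulus gap
distribution centered at the set size; any schedule with an immediate
same-odor run longer than ``MAX_RUN`` is reshuffled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import models
from .trials import COLUMNS, validate_trials

MAX_RUN = 3


class TaskConfigError(ValueError):
    """Invalid session specification."""


@dataclass(frozen=True)
class SessionSpec:
    """Configuration of one synthetic session."""

    set_size: int = 2
    presentations_per_odor: int = 200
    include_readiness_block: bool = False
    readiness_threshold: float = 0.70
    readiness_window: int = 200
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.set_size not in (2, 4):
            raise TaskConfigError(f"set_size must be 2 or 4, got {self.set_size}")
        if self.presentations_per_odor < 1:
            raise TaskConfigError("presentations_per_odor must be >= 1")
        if not 0.0 <= self.readiness_threshold <= 1.0:
            raise TaskConfigError("readiness_threshold must be in [0, 1]")

    @property
    def n_trials(self) -> int:
        return self.set_size * self.presentations_per_odor


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered stimulus identities plus the odor -> rewarded-side map."""

    odor_ids: tuple[str, ...]
    correct_side: dict[str, str]

    def __len__(self) -> int:
        return len(self.odor_ids)


def build_schedule(spec: SessionSpec) -> StimulusSchedule:
    """Build a pseudorandom interleaved schedule for a session spec.

    Each odor appears exactly ``presentations_per_odor`` times and the
    correct sides are balanced (half the odors rewarded left, half
    right).  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    odors = [f"odor{i}" for i in range(spec.set_size)]
    sides = ["L"] * (spec.set_size // 2) + ["R"] * (spec.set_size // 2)
    correct = dict(zip(odors, sides))

    while True:
        order: list[str] = []
        for _ in range(spec.presentations_per_odor):
            block = list(odors)
            rng.shuffle(block)
            order.extend(block)
        if _max_run(order) <= MAX_RUN:
            return StimulusSchedule(odor_ids=tuple(order), correct_side=correct)


def _max_run(order: list[str]) -> int:
    run = best = 1
    for a, b in zip(order, order[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def same_stimulus_gaps(schedule: StimulusSchedule) -> np.ndarray:
    """Gaps (in trials) between successive presentations of the same stimulus."""
    last: dict[str, int] = {}
    gaps: list[int] = []
    for t, o in enumerate(schedule.odor_ids):
        if o in last:
            gaps.append(t - last[o])
        last[o] = t
    return np.asarray(gaps)


def simulate_session(
    schedule: StimulusSchedule,
    params: dict[str, float],
    model: str | models.ModelSpec = models.WINNING_MODEL,
    seed: int | None = None,
    session_id: str = "sim0",
) -> pd.DataFrame:
    """Simulate an agent on a schedule; returns a validated trial table.

    Per trial: choice sampled from the model policy given the current
    value table and the previous trial's type; reward deterministic from
    the correct side; then forgetting decay (all values) followed by the
    delta-rule update of the chosen pair.
    """
    spec = models.get_model(model)
    full = spec.validate_params(params)
    rng = np.random.default_rng(seed)
    odors = sorted(set(schedule.odor_ids), key=schedule.odor_ids.index)
    Q = {o: np.array([models.Q0, models.Q0]) for o in odors}

    rows = []
    prev_odor = prev_choice = prev_reward = None
    for t, o in enumerate(schedule.odor_ids):
        if prev_odor is None:
            ttype = models.NO_BIAS
        else:
            ttype = models.classify_trial_type(prev_odor, o, prev_reward)
        p = models.choice_probabilities(Q[o], ttype, prev_choice, full)
        a = int(rng.random() < p[1])  # 0 = L, 1 = R
        choice = "LR"[a]
        reward = int(choice == schedule.correct_side[o])
        if full["phi"] > 0:
            for oo in odors:
                Q[oo] = models.apply_forgetting(Q[oo], full)
        Q[o][a] = models.update_value(Q[o][a], reward, full)
        rows.append((session_id, t, o, schedule.correct_side[o], choice, reward))
        prev_odor, prev_choice, prev_reward = o, a, reward
    df = pd.DataFrame(rows, columns=COLUMNS)
    return validate_trials(df)


# ---------------------------------------------------------------------------
# ground-truth priors for recovery / identifiability studies

#: distribution kinds: ("uniform", lo, hi), ("loguniform", lo, hi), ("point", v)
Distribution = tuple


@dataclass(frozen=True)
class GroundTruthPrior:
    """Sampling distributions for generating parameters in simulation studies.

    Defaults span the parameter regimes typical of fitted rodent
    sessions without unidentifiable corners: moderate positive learning
    rates, softmax beta log-uniform over an order of magnitude, and
    non-negative strategy weights below 1.  Tied parameters (e.g. s4 in
    the winning model) are resolved by the model spec, not sampled.
    """

    distributions: dict[str, Distribution] = field(
        default_factory=lambda: {
            "alpha_plus": ("uniform", 0.02, 0.8),
            "alpha_minus": ("uniform", 0.2, 0.8),
            "beta": ("loguniform", 0.5, 10.0),
            "phi": ("uniform", 0.0, 0.3),
            "s1": ("uniform", 0.0, 0.6),
            "s2": ("uniform", 0.0, 1.0),
            "s3": ("uniform", 0.0, 0.6),
            "s4": ("uniform", 0.0, 1.0),
        }
    )

    def mean(self, name: str) -> float:
        """Analytic mean of a marginal (for calibration checks)."""
        kind, *args = self.distributions[name]
        if kind == "uniform":
            lo, hi = args
            return (lo + hi) / 2
        if kind == "loguniform":
            lo, hi = args
            return (hi - lo) / np.log(hi / lo)
        if kind == "point":
            return args[0]
        raise TaskConfigError(f"unknown distribution kind {kind!r}")

    def _draw(self, name: str, rng: np.random.Generator) -> float:
        kind, *args = self.distributions[name]
        if kind == "uniform":
            return float(rng.uniform(*args))
        if kind == "loguniform":
            lo, hi = args
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        if kind == "point":
            return float(args[0])
        raise TaskConfigError(f"unknown distribution kind {kind!r}")


def sample_ground_truth(
    prior: GroundTruthPrior,
    n_sessions: int,
    seed: int | None = None,
    model: str | models.ModelSpec = models.WINNING_MODEL,
) -> list[dict[str, float]]:
    """Draw full parameter dicts for ``n_sessions`` sessions of a model.

    Free parameters are sampled from the prior; fixed and tied parameters
    are resolved from the model spec.  Reproducible given ``seed``.
    """
    if n_sessions < 1:
        raise TaskConfigError("n_sessions must be >= 1")
    spec = models.get_model(model)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_sessions):
        free = [prior._draw(name, rng) for name in spec.free]
        out.append(spec.resolve(free))
    return out


def readiness_check(records: pd.DataFrame, spec: SessionSpec) -> bool:
    """Gate on a two-odor readiness block.

    Pass iff, within the first ``spec.readiness_window`` trials, the
    fraction correct is at least ``spec.readiness_threshold`` for *each*
    of the two odors.
    """
    df = validate_trials(records, single_session=True).sort_values("trial_index")
    odors = df["odor_id"].unique()
    if len(odors) > 2:
        raise TaskConfigError(f"readiness block must contain exactly 2 odors, got {len(odors)}")
    window = df.head(spec.readiness_window)
    if window["odor_id"].nunique() < 2:
        return False
    acc = window.groupby("odor_id")["reward"].mean()
    return bool((acc >= spec.readiness_threshold).all())


def generate_sessions(
    n_sessions: int,
    spec: SessionSpec,
    params_list: list[dict[str, float]],
    model: str | models.ModelSpec = models.WINNING_MODEL,
    seed: int | None = None,
    session_prefix: str = "sim",
) -> pd.DataFrame:
    """Simulate a cohort: one fresh schedule + agent per parameter set."""
    if len(params_list) != n_sessions:
        raise TaskConfigError("params_list length must equal n_sessions")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_sessions)
    frames = []
    for i, params in enumerate(params_list):
        sched_seed = int(children[2 * i].generate_state(1)[0] % (2**31))
        agent_seed = int(children[2 * i + 1].generate_state(1)[0] % (2**31))
        sched = build_schedule(replace(spec, seed=sched_seed))
        frames.append(
            simulate_session(sched, params, model, seed=agent_seed, session_id=f"{session_prefix}{i}")
        )
    return pd.concat(frames, ignore_index=True)
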