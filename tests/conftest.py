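"""Shared fixtures and the independent brute-force likelihood oracle.

The oracle re-derives the session likelihood from the model definition
with plain Python floats and dictionaries, enumerating the value-state
chain trial by trial.  It shares no code with the package's likelihood
path and exists so the two can be compared to tight tolerance.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from rlstrat import task
from rlstrat.trials import COLUMNS


def make_session(odors, choices, correct_sides, session_id="s0"):
    """Build a validated-shape trial table from parallel per-trial lists."""
    rows = []
    for t, (o, c) in enumerate(zip(odors, choices)):
        cs = correct_sides[o]
        rows.append((session_id, t, o, cs, c, int(c == cs)))
    return pd.DataFrame(rows, columns=COLUMNS)


def random_session(rng, n_trials=10, n_odors=2, session_id="r0"):
    """A random (agent-free) session: random stimuli and random choices."""
    odors = [f"o{rng.integers(n_odors)}" for _ in range(n_trials)]
    sides = {f"o{i}": ("L" if i % 2 == 0 else "R") for i in range(n_odors)}
    choices = [("L" if rng.random() < 0.5 else "R") for _ in range(n_trials)]
    return make_session(odors, choices, sides, session_id)


def oracle_negll(df: pd.DataFrame, params: dict, q0: float = 0.5) -> float:
    """Brute-force trial-by-trial likelihood trace (independent of the package).

    Implements: softmax over Q(o, a) + b_i * 1{a == a_prev} scaled by beta,
    with b = (-s1, s2, s3, s4) indexed by the 2x2 of (same stimulus,
    previous reward); forgetting decay of all values toward q0, then the
    sign-gated delta-rule update of the chosen pair.
    """
    df = df.sort_values("trial_index")
    Q: dict = {}
    total = 0.0
    prev = None  # (odor, choice_index, reward)
    for _, row in df.iterrows():
        o, a = row["odor_id"], (0 if row["choice"] == "L" else 1)
        r = int(row["reward"])
        if o not in Q:
            Q[o] = [q0, q0]
        u = [Q[o][0], Q[o][1]]
        if prev is not None:
            po, pa, pr = prev
            if o == po and pr == 1:
                b = params["s4"]
            elif o == po:
                b = params["s3"]
            elif pr == 1:
                b = params["s2"]
            else:
                b = -params["s1"]
            u[pa] += b
        e0 = math.exp(params["beta"] * (u[0] - max(u)))
        e1 = math.exp(params["beta"] * (u[1] - max(u)))
        p = (e0 if a == 0 else e1) / (e0 + e1)
        total -= math.log(max(p, 1e-12))
        if params["phi"] > 0:
            for oo in Q:
                Q[oo][0] += params["phi"] * (q0 - Q[oo][0])
                Q[oo][1] += params["phi"] * (q0 - Q[oo][1])
        delta = r - Q[o][a]
        alpha = params["alpha_plus"] if delta > 0 else params["alpha_minus"]
        Q[o][a] += alpha * delta
        prev = (o, a, r)
    return total


def random_full_params(rng, model_spec):
    """Random in-bounds full parameter dict consistent with a model spec."""
    draws = {
        "alpha_plus": rng.uniform(0, 1),
        "alpha_minus": rng.uniform(0, 1),
        "beta": rng.uniform(0, 10),
        "phi": rng.uniform(0, 1),
        "s1": rng.uniform(-2, 2),
        "s2": rng.uniform(-2, 2),
        "s3": rng.uniform(-2, 2),
        "s4": rng.uniform(-2, 2),
    }
    free = [draws[name] for name in model_spec.free]
    return model_spec.resolve(free)


WINNING_PARAMS = {
    "alpha_plus": 0.1, "alpha_minus": 0.0, "beta": 5.0, "phi": 0.0,
    "s1": 0.2, "s2": 0.5, "s3": 0.2, "s4": 0.5,
}


@pytest.fixture(scope="session")
def winning_session():
    """One 200-trial set-size-2 session simulated from the winning model."""
    sched = task.build_schedule(task.SessionSpec(set_size=2, presentations_per_odor=100, seed=7))
    return task.simulate_session(sched, WINNING_PARAMS, "a0bs1232", seed=8)


@pytest.fixture(scope="session")
def small_cohort():
    """Five 120-trial sessions from the winning model with varied parameters."""
    prior = task.GroundTruthPrior()
    params = task.sample_ground_truth(prior, 5, seed=21)
    spec = task.SessionSpec(set_size=2, presentations_per_odor=60)
    return task.generate_sessions(5, spec, params, seed=22)
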