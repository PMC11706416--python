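"""Delta-rule RL model family with one-back strategy policies.

The agent learns action values Q(o, a) for each odor o and side a with a
delta rule Q <- Q + alpha * (r - Q), starting from the uninformative
Q0 = 0.5, with separate learning rates for positive (alpha_plus) and
negative (alpha_minus) prediction errors and optional forgetting
(decay of all values toward Q0 by phi each trial).  Choice follows a
softmax with inverse temperature beta over Q plus a one-back strategy
bias that depends on the trial type — the cross of (previous stimulus
same / different) x (previous trial rewarded / unrewarded):

    T1: different odor, unrewarded   (weight s1, "inappropriate lose-shift")
    T2: different odor, rewarded     (weight s2, "inappropriate win-stay")
    T3: same odor, unrewarded        (weight s3, "inappropriate lose-stay")
    T4: same odor, rewarded          (weight s4, "win-stay")

    P(a | o, Ti) ∝ exp(beta * (Q(o, a) + b_i * I(a == a_{t-1})))

Reported strategy weights follow the convention where each s_i is
positive in the direction its name describes: for T1 the named direction
is *shifting*, so the effective repeat-action bias is b_1 = -s1, while
b_2 = +s2, b_3 = +s3, b_4 = +s4.  The first trial of a session has no
predecessor and receives no bias term.

Model variants are named by a compact registry grammar, e.g. the winning
model ``a0bs1232``: free alpha_plus (``a``), alpha_minus fixed to 0
(``0``), free beta (``b``), and strategy slots ``s1232`` meaning s1, s2,
s3 free with s4 tied to s2.  See :func:`parse_model`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .trials import session_arrays, validate_trials

Q0 = 0.5
PARAM_NAMES = ("alpha_plus", "alpha_minus", "beta", "phi", "s1", "s2", "s3", "s4")

#: Optimization box; alpha/phi are probabilities-per-trial, beta is capped
#: generously, strategy weights are unbounded in the model but boxed for fitting.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha_plus": (0.0, 1.0),
    "alpha_minus": (0.0, 1.0),
    "beta": (0.0, 50.0),
    "phi": (0.0, 1.0),
    "s1": (-5.0, 5.0),
    "s2": (-5.0, 5.0),
    "s3": (-5.0, 5.0),
    "s4": (-5.0, 5.0),
}

#: Per-trial choice probabilities are clipped here before the log.
LIK_FLOOR = 1e-12

NO_BIAS = 0  # sentinel trial type for the first trial of a session
T1, T2, T3, T4 = 1, 2, 3, 4

_CORE_RE = re.compile(r"^(?P<alpha>aa|a0)b(?:s(?P<slots>[1-4]{1,4}))?$")


class ModelError(ValueError):
    """Unknown model name or parameters inconsistent with a model."""


@dataclass(frozen=True)
class ModelSpec:
    """Which of the eight parameters are free, fixed, or tied.

    Every parameter name appears in exactly one of ``free``, ``fixed``
    or ``ties`` (tied parameter -> the free parameter it equals).
    """

    name: str
    free: tuple[str, ...]
    fixed: dict[str, float] = field(default_factory=dict)
    ties: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set(self.free) | set(self.fixed) | set(self.ties)
        if seen != set(PARAM_NAMES):
            raise ModelError(f"model {self.name!r}: parameters not partitioned: {seen}")
        for tied, target in self.ties.items():
            if target not in self.free:
                raise ModelError(f"model {self.name!r}: tie target {target!r} is not free")

    @property
    def n_free(self) -> int:
        return len(self.free)

    def resolve(self, free_values) -> dict[str, float]:
        """Expand free-parameter values into a full 8-parameter dict."""
        free_values = np.asarray(free_values, dtype=float)
        if free_values.shape != (self.n_free,):
            raise ModelError(
                f"model {self.name}: expected {self.n_free} free values, got {free_values.shape}"
            )
        params = dict(zip(self.free, free_values))
        params.update(self.fixed)
        for tied, target in self.ties.items():
            params[tied] = params[target]
        return {k: float(params[k]) for k in PARAM_NAMES}

    def validate_params(self, params: dict[str, float]) -> dict[str, float]:
        """Check bounds and tie/fixed consistency of a full parameter dict."""
        full = {k: float(params.get(k, 0.0)) for k in PARAM_NAMES}
        for k in ("alpha_plus", "alpha_minus", "phi"):
            if not 0.0 <= full[k] <= 1.0:
                raise ModelError(f"{k}={full[k]} outside [0, 1]")
        if full["beta"] < 0:
            raise ModelError(f"beta={full['beta']} must be >= 0")
        for k, v in self.fixed.items():
            if full[k] != v:
                raise ModelError(f"model {self.name}: {k} is fixed at {v}, got {full[k]}")
        for tied, target in self.ties.items():
            if full[tied] != full[target]:
                raise ModelError(f"model {self.name}: {tied} must equal {target}")
        return full

    def free_bounds(self) -> list[tuple[float, float]]:
        return [PARAM_BOUNDS[k] for k in self.free]


def parse_model(name: str) -> ModelSpec:
    """Parse a registry name into a :class:`ModelSpec`.

    Grammar: ``a`` = free alpha_plus; ``aa`` = both learning rates free;
    ``0`` = alpha_minus fixed at 0; ``b`` = free beta; ``s<digits>`` =
    strategy slots — four digits give a slot map (digit i names the slot
    that slot i is tied to, so ``s1232`` ties s4 to s2), fewer digits
    list the free slots with the rest fixed at 0; suffix ``-nos`` = all
    strategies fixed at 0; suffix ``-phi`` = forgetting free (otherwise
    phi is fixed at 0).
    """
    tokens = name.split("-")
    core, flags = tokens[0], tokens[1:]
    for f in flags:
        if f not in ("nos", "phi"):
            raise ModelError(f"unknown model flag {f!r} in {name!r}")
    m = _CORE_RE.match(core)
    if m is None:
        raise ModelError(f"cannot parse model name {name!r}")

    free: list[str] = ["alpha_plus"]
    fixed: dict[str, float] = {}
    ties: dict[str, str] = {}
    if m.group("alpha") == "aa":
        free.append("alpha_minus")
    else:
        fixed["alpha_minus"] = 0.0
    free.append("beta")
    fixed["phi"] = 0.0
    if "phi" in flags:
        del fixed["phi"]
        free.append("phi")

    slots = m.group("slots")
    if slots is not None and "nos" in flags:
        raise ModelError(f"model {name!r} mixes strategy slots with -nos")
    if slots is None:
        for i in range(1, 5):
            fixed[f"s{i}"] = 0.0
    elif len(slots) == 4:
        for i, d in enumerate(slots, start=1):
            if int(d) == i:
                free.append(f"s{i}")
            elif int(d) < i and f"s{d}" in free:
                ties[f"s{i}"] = f"s{d}"
            else:
                raise ModelError(f"model {name!r}: slot map digit {d} at position {i} invalid")
    else:
        if len(set(slots)) != len(slots):
            raise ModelError(f"model {name!r}: repeated digits in a free-slot list")
        on = {int(d) for d in slots}
        for i in range(1, 5):
            if i in on:
                free.append(f"s{i}")
            else:
                fixed[f"s{i}"] = 0.0
    return ModelSpec(name=name, free=tuple(free), fixed=fixed, ties=ties)


def model_name(spec: ModelSpec) -> str:
    """Emit the canonical registry name for a spec (inverse of parse_model)."""
    parts = ["aa" if "alpha_minus" in spec.free else "a0", "b"]
    s_free = [i for i in range(1, 5) if f"s{i}" in spec.free]
    s_tied = {i: int(spec.ties[f"s{i}"][1]) for i in range(1, 5) if f"s{i}" in spec.ties}
    suffix = ""
    if not s_free and not s_tied:
        suffix = "-nos"
    elif s_tied or s_free == [1, 2, 3, 4]:
        digits = "".join(str(s_tied.get(i, i)) for i in range(1, 5))
        parts.append(f"s{digits}")
    else:
        parts.append("s" + "".join(str(i) for i in s_free))
    name = "".join(parts) + suffix
    if "phi" in spec.free:
        name += "-phi"
    return name


#: The shipped model registry, ordered roughly by complexity.
REGISTRY_NAMES = (
    "a0b-nos",
    "a0bs1",
    "a0bs13",
    "a0bs1232",
    "a0bs1234",
    "aabs1232",
    "a0bs1232-phi",
)
REGISTRY: dict[str, ModelSpec] = {n: parse_model(n) for n in REGISTRY_NAMES}
WINNING_MODEL = "a0bs1232"


def get_model(model: str | ModelSpec) -> ModelSpec:
    if isinstance(model, ModelSpec):
        return model
    if model in REGISTRY:
        return REGISTRY[model]
    return parse_model(model)


# ---------------------------------------------------------------------------
# state-update primitives


def update_value(q: float, reward: int, params: dict[str, float]) -> float:
    """Delta-rule update of the chosen (odor, action) value.

    The learning rate is gated on the sign of the prediction error:
    alpha_plus if r - q > 0, alpha_minus otherwise.
    """
    delta = reward - q
    alpha = params["alpha_plus"] if delta > 0 else params["alpha_minus"]
    return q + alpha * delta


def apply_forgetting(table: np.ndarray, params: dict[str, float]) -> np.ndarray:
    """Decay every odor-action value toward Q0 by factor phi (returns a copy)."""
    phi = params["phi"]
    return table + phi * (Q0 - table)


def classify_trial_type(prev_odor, cur_odor, prev_reward: int) -> int:
    """Label a trial T1..T4 by (stimulus changed?, previous reward)."""
    same = prev_odor == cur_odor
    if same:
        return T4 if prev_reward == 1 else T3
    return T2 if prev_reward == 1 else T1


def effective_biases(params: dict[str, float]) -> tuple[float, float, float, float]:
    """Repeat-action bias per trial type under the reported sign convention.

    s1 names a *shift* tendency, so its repeat-action bias is negated.
    """
    return (-params["s1"], params["s2"], params["s3"], params["s4"])


def choice_probabilities(
    q_pair,
    trial_type: int,
    prev_choice: int | None,
    params: dict[str, float],
) -> np.ndarray:
    """Softmax probabilities over (L, R) for one trial.

    ``q_pair`` is (Q(o, L), Q(o, R)); ``prev_choice`` is 0 for L, 1 for R,
    or None on the no-bias first trial (trial_type == NO_BIAS).
    """
    u = np.asarray(q_pair, dtype=float).copy()
    if trial_type != NO_BIAS:
        if prev_choice not in (0, 1):
            raise ModelError("prev_choice must be 0 or 1 when a previous trial exists")
        u[prev_choice] += effective_biases(params)[trial_type - 1]
    z = params["beta"] * (u - u.max())
    e = np.exp(z)
    return e / e.sum()


# ---------------------------------------------------------------------------
# session likelihood (JIT core + public wrapper)


@njit(cache=True)
def _session_negll(odor, choice, reward, alpha_p, alpha_m, beta, phi, b1, b2, b3, b4, n_odors):
    Q = np.full((n_odors, 2), 0.5)
    nll = 0.0
    n = odor.shape[0]
    for t in range(n):
        o = odor[t]
        u0 = Q[o, 0]
        u1 = Q[o, 1]
        if t > 0:
            same = odor[t] == odor[t - 1]
            rew = reward[t - 1] == 1
            if same and rew:
                b = b4
            elif same:
                b = b3
            elif rew:
                b = b2
            else:
                b = b1
            if choice[t - 1] == 0:
                u0 += b
            else:
                u1 += b
        # chosen-side logit, so tiny probabilities keep full relative precision
        z = beta * (u1 - u0) if choice[t] == 1 else beta * (u0 - u1)
        p = 1.0 / (1.0 + np.exp(-z))
        if p < LIK_FLOOR:
            p = LIK_FLOOR
        nll -= np.log(p)
        if phi > 0.0:
            for oo in range(n_odors):
                Q[oo, 0] += phi * (0.5 - Q[oo, 0])
                Q[oo, 1] += phi * (0.5 - Q[oo, 1])
        q = Q[o, choice[t]]
        delta = reward[t] - q
        if delta > 0.0:
            Q[o, choice[t]] = q + alpha_p * delta
        else:
            Q[o, choice[t]] = q + alpha_m * delta
    return nll


def negative_log_likelihood(records, params: dict[str, float], model: str | ModelSpec) -> float:
    """Negative log-likelihood of a single ordered session under a model.

    The value state evolves as in simulation: policy, then (if the model
    frees phi) forgetting decay of all values, then the delta-rule update
    of the chosen pair.  Per-trial probabilities are clipped at
    ``LIK_FLOOR`` before the log.
    """
    spec = get_model(model)
    full = spec.validate_params(params)
    df = validate_trials(records, single_session=True)
    odor, choice, reward, n_odors = session_arrays(df)
    b1, b2, b3, b4 = effective_biases(full)
    return float(
        _session_negll(
            odor, choice, reward,
            full["alpha_plus"], full["alpha_minus"], full["beta"], full["phi"],
            b1, b2, b3, b4, n_odors,
        )
    )


def _negll_from_arrays(odor, choice, reward, n_odors, full: dict[str, float]) -> float:
    """Likelihood entry point for the optimizer (skips table validation)."""
    b1, b2, b3, b4 = effective_biases(full)
    return float(
        _session_negll(
            odor, choice, reward,
            full["alpha_plus"], full["alpha_minus"], full["beta"], full["phi"],
            b1, b2, b3, b4, n_odors,
        )
    )
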