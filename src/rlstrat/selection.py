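"""Group-level model comparison.

Random-effects Bayesian model selection treats each session as drawn
from a population in which model frequencies r follow a Dirichlet
distribution.  Given per-session approximate log model evidences
(-BIC/2), a variational update yields the Dirichlet concentration,
posterior expected frequencies, exceedance probabilities (xp), the
Bayesian omnibus risk (bor — the posterior probability that all models
are equally frequent), and protected exceedance probabilities

    pxp_k = (1 - bor) * xp_k + bor / K.

Also provides per-session BIC selection and simulate->fit->select
confusion matrices for model identifiability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betainc, gammaln, logsumexp, psi
from sklearn.base import BaseEstimator

from . import models, task
from .fitting import fit_cohort


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class BMSResult:
    """Group Bayesian model selection output (arrays ordered like model_names)."""

    model_names: tuple[str, ...]
    alpha: np.ndarray
    expected_frequency: np.ndarray
    xp: np.ndarray
    bor: float
    pxp: np.ndarray
    converged: bool
    n_iter: int

    def to_dict(self) -> dict:
        return {
            "model_names": list(self.model_names),
            "alpha": self.alpha.tolist(),
            "expected_frequency": self.expected_frequency.tolist(),
            "xp": self.xp.tolist(),
            "bor": self.bor,
            "pxp": self.pxp.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


def evidence_from_fits(fits: pd.DataFrame, model_names: list[str] | None = None) -> pd.DataFrame:
    """Sessions x models table of approximate log evidence, -BIC/2."""
    if model_names is None:
        model_names = list(dict.fromkeys(fits["model"]))
    wide = fits.pivot(index="session_id", columns="model", values="bic")
    missing = [m for m in model_names if m not in wide.columns]
    if missing:
        raise SelectionError(f"fits table lacks models {missing}")
    ev = -wide[model_names] / 2.0
    if ev.isna().any().any():
        bad = [(i, c) for i, c in zip(*np.nonzero(ev.isna().to_numpy()))]
        raise SelectionError(f"non-finite evidence for session x model cells {bad[:5]}")
    return ev


def exceedance_probability(
    alpha: np.ndarray,
    n_samples: int = 1_000_000,
    seed: int | None = None,
    method: str = "sampling",
) -> np.ndarray:
    """P(r_k is the largest frequency) under Dirichlet(alpha).

    ``method="sampling"`` (default) uses seeded Monte-Carlo draws;
    ``method="exact"`` is available for K=2 via the Beta CDF.
    """
    alpha = np.asarray(alpha, dtype=float)
    K = alpha.size
    if method == "exact":
        if K != 2:
            raise SelectionError("exact exceedance only implemented for K=2")
        p2 = betainc(alpha[0], alpha[1], 0.5)  # P(r1 < 0.5)
        return np.array([1.0 - p2, p2])
    rng = np.random.default_rng(seed)
    counts = np.zeros(K)
    chunk = 100_000
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        draws = rng.dirichlet(alpha, size=m)
        winners = np.argmax(draws, axis=1)
        counts += np.bincount(winners, minlength=K)
        done += m
    return counts / n_samples


def _dirichlet_elbo(L: np.ndarray, g: np.ndarray, alpha: np.ndarray, alpha0: np.ndarray) -> float:
    """Variational lower bound of the random-effects model."""
    dig = psi(alpha) - psi(alpha.sum())
    e_lik = float(np.sum(g * L))
    e_assign = float(np.sum(g * dig))
    e_prior = float(gammaln(alpha0.sum()) - gammaln(alpha0).sum() + np.sum((alpha0 - 1) * dig))
    h_r = float(gammaln(alpha.sum()) - gammaln(alpha).sum() + np.sum((alpha - 1) * dig))
    with np.errstate(divide="ignore", invalid="ignore"):
        h_m = float(np.sum(np.where(g > 0, g * np.log(g), 0.0)))
    return e_lik + e_assign + e_prior - h_r - h_m


def group_bms(
    evidence: pd.DataFrame | np.ndarray,
    alpha0: float = 1.0,
    seed: int | None = None,
    n_samples: int = 1_000_000,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> BMSResult:
    """Random-effects Bayesian model selection over an evidence matrix.

    ``evidence`` is sessions x models log model evidence (any per-session
    additive constant cancels).  Exceedance probabilities are estimated
    by seeded Dirichlet sampling; bor compares the variational free
    energy of the random-effects model against the exact evidence of the
    null model in which all frequencies equal 1/K.
    """
    if isinstance(evidence, pd.DataFrame):
        names = tuple(str(c) for c in evidence.columns)
        L = evidence.to_numpy(dtype=float)
    else:
        L = np.asarray(evidence, dtype=float)
        names = tuple(f"m{k}" for k in range(L.shape[1]))
    if L.ndim != 2 or L.shape[0] < 1 or L.shape[1] < 2:
        raise SelectionError("evidence must be (n_sessions >= 1) x (n_models >= 2)")
    if not np.isfinite(L).all():
        raise SelectionError("evidence contains non-finite entries")
    n, K = L.shape
    L = L - L.max(axis=1, keepdims=True)  # per-session constants cancel

    a0 = np.full(K, float(alpha0))
    alpha = a0.copy()
    converged = False
    for it in range(1, max_iter + 1):
        logu = L + psi(alpha) - psi(alpha.sum())
        logu -= logu.max(axis=1, keepdims=True)
        g = np.exp(logu)
        g /= g.sum(axis=1, keepdims=True)
        alpha_new = a0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new

    freq = alpha / alpha.sum()
    xp = exceedance_probability(alpha, n_samples=n_samples, seed=seed)

    f1 = _dirichlet_elbo(L, g, alpha, a0)
    f0 = float(np.sum(logsumexp(L, axis=1) - np.log(K)))
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pxp = (1.0 - bor) * xp + bor / K
    return BMSResult(
        model_names=names, alpha=alpha, expected_frequency=freq,
        xp=xp, bor=bor, pxp=pxp, converged=converged, n_iter=it,
    )


class GroupBMS(BaseEstimator):
    """Estimator wrapper around :func:`group_bms`.

    ``fit(evidence)`` stores ``alpha_``, ``expected_frequency_``, ``xp_``,
    ``bor_``, ``pxp_``, ``model_names_``, ``best_model_``.
    """

    def __init__(self, alpha0: float = 1.0, seed: int | None = None,
                 n_samples: int = 1_000_000, tol: float = 1e-6, max_iter: int = 1000):
        self.alpha0 = alpha0
        self.seed = seed
        self.n_samples = n_samples
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None) -> "GroupBMS":
        res = group_bms(X, alpha0=self.alpha0, seed=self.seed,
                        n_samples=self.n_samples, tol=self.tol, max_iter=self.max_iter)
        self.result_ = res
        self.model_names_ = res.model_names
        self.alpha_ = res.alpha
        self.expected_frequency_ = res.expected_frequency
        self.xp_ = res.xp
        self.bor_ = res.bor
        self.pxp_ = res.pxp
        self.converged_ = res.converged
        self.best_model_ = res.model_names[int(np.argmax(res.pxp))]
        return self


def select_by_bic(fits: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Per-session BIC winner and per-model mean BIC.

    Requires every session fitted under every model; ties go to the
    model with fewer free parameters (then lexical order).
    """
    model_names = list(dict.fromkeys(fits["model"]))
    wide = fits.pivot(index="session_id", columns="model", values="bic")[model_names]
    if wide.isna().any().any():
        missing = [
            (sid, m) for sid in wide.index for m in model_names if pd.isna(wide.loc[sid, m])
        ]
        raise SelectionError(f"missing session x model fits: {missing[:10]}")
    if "n_free" in fits.columns:
        n_free = fits.groupby("model")["n_free"].first().to_dict()
    else:
        n_free = {m: models.get_model(m).n_free for m in model_names}
    winners = {}
    for sid, row in wide.iterrows():
        best = min(model_names, key=lambda m: (row[m], n_free[m], m))
        winners[sid] = best
    return pd.Series(winners, name="winner"), wide.mean(axis=0).rename("mean_bic")


def confusion_study(
    model_names: list[str],
    prior: task.GroundTruthPrior | None = None,
    session_spec: task.SessionSpec | None = None,
    n_cohorts: int = 20,
    sessions_per_cohort: int = 1,
    n_starts: int = 10,
    selector: str = "bic",
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate->fit->select identifiability study.

    For each generating model: draw parameters from the prior, simulate
    ``sessions_per_cohort`` sessions per cohort, fit all candidate
    models, select a winner per cohort (mean per-session BIC, or group
    BMS when the cohort has several sessions), and tally.  Returns a
    generating x selected count table whose rows sum to ``n_cohorts``.
    """
    prior = prior or task.GroundTruthPrior()
    session_spec = session_spec or task.SessionSpec(set_size=2, presentations_per_odor=200)
    if selector not in ("bic", "bms"):
        raise SelectionError(f"unknown selector {selector!r}")
    ss = np.random.SeedSequence(seed)
    counts = pd.DataFrame(0, index=model_names, columns=model_names, dtype=int)
    for gen in model_names:
        for _ in range(n_cohorts):
            child = ss.spawn(3)
            seeds = [int(c.generate_state(1)[0] % (2**31)) for c in child]
            params = task.sample_ground_truth(prior, sessions_per_cohort, seed=seeds[0], model=gen)
            sessions = task.generate_sessions(
                sessions_per_cohort, session_spec, params, model=gen, seed=seeds[1]
            )
            fits = fit_cohort(sessions, model_names, n_starts=n_starts, seed=seeds[2])
            if selector == "bms" and sessions_per_cohort > 1:
                res = group_bms(evidence_from_fits(fits, model_names),
                                seed=seeds[2], n_samples=100_000)
                winner = res.model_names[int(np.argmax(res.pxp))]
            else:
                _, mean_bic = select_by_bic(fits)
                n_free = {m: models.get_model(m).n_free for m in model_names}
                winner = min(model_names, key=lambda m: (mean_bic[m], n_free[m], m))
            counts.loc[gen, winner] += 1
    counts.index.name = "generating"
    counts.columns.name = "selected"
    return counts
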