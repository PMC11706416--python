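"""Per-session maximum-likelihood fitting of the RL + strategy models.

`RLChoiceModel` is a scikit-learn-style estimator: ``fit`` runs bounded
multi-start optimization of the session negative log-likelihood over the
model's free parameters; fitted attributes carry the parameter vector and
information criteria.  ``fit_session`` / ``fit_cohort`` are thin
functional wrappers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from . import models
from .trials import session_arrays, validate_trials

FIT_COLUMNS = (
    ["session_id", "model", "negll", "aic", "bic", "n_trials", "n_free", "converged", "n_starts"]
    + list(models.PARAM_NAMES)
)


class FitError(RuntimeError):
    pass


def information_criteria(negll: float, n_free: int, n_trials: int) -> tuple[float, float]:
    """(AIC, BIC) from a fitted negative log-likelihood."""
    aic = 2.0 * negll + 2.0 * n_free
    bic = 2.0 * negll + n_free * np.log(n_trials)
    return float(aic), float(bic)


class RLChoiceModel(BaseEstimator):
    """Maximum-likelihood fit of one RL + one-back-strategy model to a session.

    Parameters
    ----------
    model : str or ModelSpec, default ``"a0bs1232"``
        Registry name (see :func:`rlstrat.models.parse_model`).
    n_starts : int
        Number of random restarts; start points are drawn uniformly in
        the bound box from ``seed``.  Starts are drawn sequentially from
        one stream, so the best objective over ``n`` starts can only
        improve as ``n`` grows (for a fixed seed).
    seed : int or None
        Seed for the restart stream.
    min_trials : int
        Floor on usable session length.
    tol : float
        Optimizer function tolerance (L-BFGS-B ``ftol``).

    Attributes (after ``fit``)
    --------------------------
    params_ : dict mapping all eight parameter names to fitted values
        (fixed and tied entries resolved).
    free_params_ : ndarray of the free-parameter values, in spec order.
    negll_, aic_, bic_ : float
    n_trials_, n_free_ : int
    converged_ : bool — True if any restart converged.
    """

    def __init__(
        self,
        model: str | models.ModelSpec = models.WINNING_MODEL,
        n_starts: int = 20,
        seed: int | None = None,
        min_trials: int = 20,
        tol: float = 1e-9,
    ):
        self.model = model
        self.n_starts = n_starts
        self.seed = seed
        self.min_trials = min_trials
        self.tol = tol

    def fit(self, X: pd.DataFrame, y=None) -> "RLChoiceModel":
        """Fit to a single ordered session (trial table)."""
        spec = models.get_model(self.model)
        df = validate_trials(X, single_session=True)
        if len(df) < self.min_trials:
            raise FitError(f"session has {len(df)} trials; floor is {self.min_trials}")
        odor, choice, reward, n_odors = session_arrays(df)
        bounds = spec.free_bounds()
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])

        def objective(x: np.ndarray) -> float:
            return models._negll_from_arrays(odor, choice, reward, n_odors, spec.resolve(x))

        rng = np.random.default_rng(self.seed)
        best_x, best_f, converged = None, np.inf, False
        for _ in range(max(1, int(self.n_starts))):
            x0 = rng.uniform(lo, hi)
            try:
                res = minimize(
                    objective, x0, method="L-BFGS-B", bounds=bounds,
                    options={"ftol": self.tol, "maxiter": 500},
                )
            except FloatingPointError:  # pragma: no cover - defensive
                continue
            if np.isfinite(res.fun) and res.fun < best_f:
                best_x, best_f = np.asarray(res.x, dtype=float), float(res.fun)
            converged = converged or bool(res.success)
        if best_x is None:
            best_x = (lo + hi) / 2.0
            best_f = float(objective(best_x))
            converged = False

        self.model_spec_ = spec
        self.free_params_ = best_x
        self.params_ = spec.resolve(best_x)
        self.negll_ = best_f
        self.n_trials_ = len(df)
        self.n_free_ = spec.n_free
        self.aic_, self.bic_ = information_criteria(best_f, spec.n_free, len(df))
        self.converged_ = converged
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Per-trial choice probabilities over (L, R) under the fitted parameters."""
        self._check_fitted()
        df = validate_trials(X, single_session=True).sort_values("trial_index")
        full = self.params_
        odors = df["odor_id"].tolist()
        choices = (df["choice"] == "R").astype(int).tolist()
        rewards = df["reward"].tolist()
        Q = {o: np.array([models.Q0, models.Q0]) for o in dict.fromkeys(odors)}
        out = np.empty((len(df), 2))
        for t, o in enumerate(odors):
            if t == 0:
                ttype, prev = models.NO_BIAS, None
            else:
                ttype = models.classify_trial_type(odors[t - 1], o, rewards[t - 1])
                prev = choices[t - 1]
            out[t] = models.choice_probabilities(Q[o], ttype, prev, full)
            if full["phi"] > 0:
                for oo in Q:
                    Q[oo] = models.apply_forgetting(Q[oo], full)
            Q[o][choices[t]] = models.update_value(Q[o][choices[t]], rewards[t], full)
        return out

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Mean per-trial log-likelihood (higher is better)."""
        self._check_fitted()
        nll = models.negative_log_likelihood(X, self.params_, self.model_spec_)
        return -nll / len(X)

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise FitError("estimator is not fitted")


def fit_session(
    records: pd.DataFrame,
    model: str | models.ModelSpec = models.WINNING_MODEL,
    n_starts: int = 20,
    seed: int | None = None,
    **kwargs,
) -> RLChoiceModel:
    """Fit one model to one session; returns the fitted estimator."""
    return RLChoiceModel(model=model, n_starts=n_starts, seed=seed, **kwargs).fit(records)


def fit_cohort(
    sessions: pd.DataFrame,
    model_names: list[str],
    n_starts: int = 20,
    seed: int | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Fit every model to every session; one row per (session, model).

    A failed cell is recorded with ``converged=False`` and NaN criteria
    rather than aborting the cohort.  Deterministic given ``seed``: each
    (session, model) cell gets its own child seed in table order.
    """
    if len(model_names) == 0:
        raise FitError("need at least one model")
    session_ids = list(dict.fromkeys(sessions["session_id"])) if len(sessions) else []
    ss = np.random.SeedSequence(seed)
    rows = []
    for sid in session_ids:
        sdf = sessions[sessions["session_id"] == sid]
        for name in model_names:
            cell_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            row = {"session_id": sid, "model": name, "n_starts": n_starts}
            try:
                est = fit_session(sdf, name, n_starts=n_starts, seed=cell_seed, **kwargs)
                row.update(
                    negll=est.negll_, aic=est.aic_, bic=est.bic_,
                    n_trials=est.n_trials_, n_free=est.n_free_, converged=est.converged_,
                    **est.params_,
                )
            except FitError:
                row.update(
                    negll=np.nan, aic=np.nan, bic=np.nan,
                    n_trials=len(sdf), n_free=models.get_model(name).n_free, converged=False,
                    **{k: np.nan for k in models.PARAM_NAMES},
                )
            rows.append(row)
    return pd.DataFrame(rows, columns=FIT_COLUMNS)
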