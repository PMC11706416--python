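"""Trial-history logistic regressions on session choice accuracy.

Six per-session designs predict the probability that the current trial's
choice is correct from the previous trial's stimulus/outcome and from a
cumulative "correct history" regressor (the log-transformed count of past
reinforced choices for the current trial's odor — the incremental-RL
marker).  With R = 1{o_t == o_{t-1}} (repeat) and W = 1{r_{t-1} == 1}
(previous reward):

  1 "trial back":            correct_history, one_back (R), two_back (1{o_t == o_{t-2}})
  2 "repeat - no repeat":    correct_history, repeat (R),
                             repeat_reward (+1 R&W, -1 R&!W, 0 !R),
                             norepeat_reward (+1 !R&W, -1 !R&!W, 0 R)
  3 "reward - no reward":    correct_history, reward (W),
                             reward_repeat (+1 W&R, -1 W&!R, 0 !W),
                             noreward_repeat (+1 !W&R, -1 !W&!R, 0 W)
  4 "repeat - reward cells": correct_history + the four 0/1 cells of R x W
  5 "interaction 1":         correct_history, repeat, reward, reward_x_repeat (R*W)
  6 "interaction 2":         correct_history, repeat, reward,
                             repeat_reward (as in 2), norepeat_reward (as in 2)

Designs 2 and 3 span the same column space (they distribute the
reward x repeat interaction differently) and therefore fit identically.
Designs 4 and 6 are rank-deficient by construction once an intercept is
included (design 4's cells sum to one; design 6's two signed columns sum
to 2W - 1, collinear with the reward main effect): they are fitted via
IRLS with a pseudoinverse, which still maximizes the likelihood, and
flagged degenerate.

Trials lacking the required history are dropped (the first trial
everywhere; the first two for design 1's two-back column), then all
regressors are z-scored within session with the population (n)
denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from .trials import validate_trials

REGRESSION_IDS = (1, 2, 3, 4, 5, 6)
MIN_USABLE_TRIALS = 10
RIDGE_LAMBDA = 1e-4
SEPARATION_COEF = 30.0  # |coef| beyond this on z-scored columns flags separation


class RegressionError(ValueError):
    pass


class DegenerateDesignError(RegressionError):
    """A regressor column has zero variance and cannot be z-scored."""


@dataclass
class DesignMatrix:
    regression_id: int
    outcome: np.ndarray          # 0/1 correct indicator per included trial
    X: pd.DataFrame              # z-scored regressors (no intercept column)
    raw: pd.DataFrame            # pre-z-scoring regressors
    included_trials: np.ndarray  # trial_index values that survived history dropping
    rank_deficient: bool
    flagged: bool = False        # too few usable trials

    @property
    def n(self) -> int:
        return len(self.outcome)


def _raw_columns(df: pd.DataFrame, regression_id: int) -> tuple[pd.DataFrame, np.ndarray]:
    odor = df["odor_id"].to_numpy()
    reward = df["reward"].to_numpy()
    n = len(df)
    start = 2 if regression_id == 1 else 1
    idx = np.arange(start, n)

    # cumulative count of past reinforced choices for the current trial's odor
    hist = np.zeros(n)
    counts: dict = {}
    for t in range(n):
        hist[t] = counts.get(odor[t], 0)
        if reward[t] == 1:
            counts[odor[t]] = counts.get(odor[t], 0) + 1
    ch = np.log1p(hist[idx])

    R = (odor[idx] == odor[idx - 1]).astype(float)
    W = (reward[idx - 1] == 1).astype(float)
    cols: dict[str, np.ndarray] = {"correct_history": ch}
    if regression_id == 1:
        cols["one_back"] = R
        cols["two_back"] = (odor[idx] == odor[idx - 2]).astype(float)
    elif regression_id == 2:
        cols["repeat"] = R
        cols["repeat_reward"] = R * (2 * W - 1)
        cols["norepeat_reward"] = (1 - R) * (2 * W - 1)
    elif regression_id == 3:
        cols["reward"] = W
        cols["reward_repeat"] = W * (2 * R - 1)
        cols["noreward_repeat"] = (1 - W) * (2 * R - 1)
    elif regression_id == 4:
        cols["repeat_reward"] = R * W
        cols["repeat_noreward"] = R * (1 - W)
        cols["norepeat_reward"] = (1 - R) * W
        cols["norepeat_noreward"] = (1 - R) * (1 - W)
    elif regression_id == 5:
        cols["repeat"] = R
        cols["reward"] = W
        cols["reward_x_repeat"] = R * W
    elif regression_id == 6:
        cols["repeat"] = R
        cols["reward"] = W
        cols["repeat_reward"] = R * (2 * W - 1)
        cols["norepeat_reward"] = (1 - R) * (2 * W - 1)
    else:
        raise RegressionError(f"regression_id must be in {REGRESSION_IDS}, got {regression_id}")
    return pd.DataFrame(cols), idx


def build_design(records: pd.DataFrame, regression_id: int) -> DesignMatrix:
    """Build one of the six per-session designs (z-scored).

    Raises :class:`DegenerateDesignError` naming any zero-variance column.
    Sessions with fewer than 10 usable trials come back flagged empty.
    """
    if regression_id not in REGRESSION_IDS:
        raise RegressionError(f"regression_id must be in {REGRESSION_IDS}, got {regression_id}")
    df = validate_trials(records, single_session=True).sort_values("trial_index")
    raw, idx = _raw_columns(df, regression_id)
    outcome = df["reward"].to_numpy()[idx].astype(int)  # correct == rewarded (deterministic)
    trial_ids = df["trial_index"].to_numpy()[idx]

    if len(raw) < MIN_USABLE_TRIALS:
        return DesignMatrix(
            regression_id, outcome[:0], raw.iloc[:0], raw.iloc[:0],
            trial_ids[:0], rank_deficient=False, flagged=True,
        )
    sd = raw.std(ddof=0)
    dead = sd.index[sd == 0].tolist()
    if dead:
        raise DegenerateDesignError(
            f"regression {regression_id}: zero-variance column(s) {dead} cannot be z-scored"
        )
    X = (raw - raw.mean()) / sd
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy()]))
    return DesignMatrix(
        regression_id, outcome, X, raw, trial_ids,
        rank_deficient=rank < X.shape[1] + 1,
    )


@dataclass
class RegressionResult:
    regression_id: int
    coef: pd.Series       # includes "intercept"
    se: pd.Series         # NaN on the ridge fallback path
    negll: float
    aic: float
    bic: float
    aicc: float
    caic: float
    vif: pd.Series
    n: int
    k: int                # parameters counted for the criteria, incl. intercept
    converged: bool
    separated: bool = False
    rank_deficient: bool = False


def _criteria(negll: float, k: int, n: int) -> tuple[float, float, float, float]:
    aic = 2 * negll + 2 * k
    bic = 2 * negll + k * np.log(n)
    aicc = aic + (2 * k * (k + 1)) / (n - k - 1) if n - k - 1 > 0 else np.inf
    caic = 2 * negll + k * (np.log(n) + 1)
    return aic, bic, aicc, caic


def _vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per z-scored regressor (inf when collinear)."""
    A = X.to_numpy()
    out = {}
    n = len(X)
    for j, name in enumerate(X.columns):
        others = np.column_stack([np.ones(n), np.delete(A, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, A[:, j], rcond=None)
        resid = A[:, j] - others @ beta
        ssr = float(resid @ resid)
        sst = float(((A[:, j] - A[:, j].mean()) ** 2).sum())
        r2 = 1.0 - ssr / sst if sst > 0 else 1.0
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def fit_logistic(design: DesignMatrix) -> RegressionResult:
    """Maximum-likelihood logistic fit of one design (with intercept).

    Complete separation (diverging coefficients) triggers a
    ridge-stabilized refit (L2, lambda = 1e-4) flagged ``separated``.
    """
    if design.flagged or design.n < MIN_USABLE_TRIALS:
        raise RegressionError("design is flagged/too small to fit")
    y = design.outcome
    Xc = sm.add_constant(design.X.to_numpy(), has_constant="add")
    names = ["intercept"] + list(design.X.columns)
    k = Xc.shape[1]
    n = design.n

    converged, separated = True, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(maxiter=200)
            coef = np.asarray(res.params, dtype=float)
            se = np.asarray(res.bse, dtype=float)
            negll = -float(res.llf)
            converged = bool(res.converged)
            if (
                not np.isfinite(coef).all()
                or np.abs(coef).max() > SEPARATION_COEF
                or negll < 1e-4  # perfectly predicted outcomes
            ):
                separated = True
        except Exception:
            separated = True

    if separated or not converged:
        lr = LogisticRegression(
            C=1.0 / RIDGE_LAMBDA, solver="lbfgs", max_iter=2000
        ).fit(design.X.to_numpy(), y)
        coef = np.concatenate([lr.intercept_, lr.coef_.ravel()])
        se = np.full(k, np.nan)
        eta = Xc @ coef
        p = 1.0 / (1.0 + np.exp(-eta))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        negll = -float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        converged = False
        separated = True

    aic, bic, aicc, caic = _criteria(negll, k, n)
    return RegressionResult(
        regression_id=design.regression_id,
        coef=pd.Series(coef, index=names),
        se=pd.Series(se, index=names),
        negll=negll, aic=aic, bic=bic, aicc=aicc, caic=caic,
        vif=_vif(design.X), n=n, k=k,
        converged=converged, separated=separated,
        rank_deficient=design.rank_deficient,
    )


class TrialHistoryLogit(BaseEstimator):
    """Estimator form: build + fit one trial-history design per session.

    Fitted attributes: ``coef_``, ``se_``, ``negll_``, ``aic_``, ``bic_``,
    ``aicc_``, ``caic_``, ``vif_``, ``converged_``, ``result_``.
    """

    def __init__(self, regression_id: int = 3):
        self.regression_id = regression_id

    def fit(self, X: pd.DataFrame, y=None) -> "TrialHistoryLogit":
        design = build_design(X, self.regression_id)
        res = fit_logistic(design)
        self.design_ = design
        self.result_ = res
        self.coef_ = res.coef
        self.se_ = res.se
        self.negll_ = res.negll
        self.aic_, self.bic_, self.aicc_, self.caic_ = res.aic, res.bic, res.aicc, res.caic
        self.vif_ = res.vif
        self.converged_ = res.converged
        return self


def regressor_correlations(design: DesignMatrix) -> pd.DataFrame:
    """Pearson correlations among the z-scored regressor columns."""
    if design.flagged:
        raise RegressionError("design is flagged; no correlations")
    return design.X.corr()


def fit_sessions(
    sessions: pd.DataFrame, regression_ids=REGRESSION_IDS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit designs per session; returns (coefficients table, criteria table).

    A session x regression cell that cannot be built or fit is recorded
    with NaN criteria rather than aborting the batch.
    """
    coef_rows, crit_rows = [], []
    for sid in dict.fromkeys(sessions["session_id"]):
        sdf = sessions[sessions["session_id"] == sid]
        for rid in regression_ids:
            try:
                res = fit_logistic(build_design(sdf, rid))
            except (RegressionError, DegenerateDesignError):
                crit_rows.append({"session_id": sid, "regression_id": rid,
                                  "negll": np.nan, "aic": np.nan, "bic": np.nan,
                                  "aicc": np.nan, "caic": np.nan, "n": len(sdf),
                                  "converged": False})
                continue
            for term in res.coef.index:
                coef_rows.append({"session_id": sid, "regression_id": rid, "term": term,
                                  "estimate": res.coef[term], "se": res.se[term],
                                  "vif": res.vif.get(term, np.nan)})
            crit_rows.append({"session_id": sid, "regression_id": rid,
                              "negll": res.negll, "aic": res.aic, "bic": res.bic,
                              "aicc": res.aicc, "caic": res.caic, "n": res.n,
                              "converged": res.converged})
    return pd.DataFrame(coef_rows), pd.DataFrame(crit_rows)


def compare_regressions(sessions: pd.DataFrame, regression_ids=REGRESSION_IDS) -> pd.DataFrame:
    """Mean AIC/BIC/AICc/CAIC per regression over sessions, with winner flags."""
    _, crit = fit_sessions(sessions, regression_ids)
    means = crit.groupby("regression_id")[["aic", "bic", "aicc", "caic"]].mean()
    for c in means.columns:
        means[f"{c}_winner"] = means[c] == means[c].min()
    return means


def drop_coefficient_outliers(coef_table: pd.DataFrame, z_max: float = 3.0) -> pd.DataFrame:
    """Optional post-hoc filter: drop per-session estimates with |z| > z_max.

    Z-scores are computed across sessions within each (regression, term)
    group; intended for downstream group analyses of coefficient tables.
    """
    def keep(grp: pd.DataFrame) -> pd.DataFrame:
        sd = grp["estimate"].std(ddof=0)
        if sd == 0 or np.isnan(sd):
            return grp
        z = (grp["estimate"] - grp["estimate"].mean()) / sd
        return grp[np.abs(z) <= z_max]

    return (
        coef_table.groupby(["regression_id", "term"], group_keys=False)[coef_table.columns]
        .apply(keep)
        .reset_index(drop=True)
    )
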