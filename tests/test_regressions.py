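"""Trial-history regression designs, coding rules, fits, and comparisons."""

import numpy as np
import pandas as pd
import pytest

from rlstrat import regressions, task
from rlstrat.regressions import (
    DegenerateDesignError,
    TrialHistoryLogit,
    build_design,
    compare_regressions,
    drop_coefficient_outliers,
    fit_logistic,
    fit_sessions,
    regressor_correlations,
)

from conftest import WINNING_PARAMS, make_session, random_session


def _simulated(seed, per_odor=100, params=WINNING_PARAMS):
    sched = task.build_schedule(task.SessionSpec(2, per_odor, seed=seed))
    return task.simulate_session(sched, params, "a0bs1232", seed=seed + 1)


class TestCoding:
    def test_printed_coding_rules_on_all_history_cells(self):
        # 9 trials walking through every (repeat, prev-reward) cell with
        # growing per-odor correct history
        odors = ["X", "X", "X", "Y", "Y", "X", "Y", "Y", "X"]
        sides = {"X": "L", "Y": "R"}
        choices = ["L", "L", "R", "R", "L", "L", "R", "L", "L"]
        df = make_session(odors, choices, sides)
        rewards = df["reward"].tolist()
        assert rewards == [1, 1, 0, 1, 0, 1, 1, 0, 1]

        raw, _ = regressions._raw_columns(df, 3)
        raw = raw.reset_index(drop=True)
        for i, t in enumerate(range(1, 9)):
            R = int(odors[t] == odors[t - 1])
            W = int(rewards[t - 1] == 1)
            hist = sum(
                1 for u in range(t) if odors[u] == odors[t] and rewards[u] == 1
            )
            assert raw.loc[i, "correct_history"] == pytest.approx(np.log1p(hist))
            assert raw.loc[i, "reward"] == W
            assert raw.loc[i, "reward_repeat"] == (0 if W == 0 else (1 if R else -1))
            assert raw.loc[i, "noreward_repeat"] == (0 if W == 1 else (1 if R else -1))

        d2 = regressions._raw_columns(df, 2)[0].reset_index(drop=True)
        d4 = regressions._raw_columns(df, 4)[0].reset_index(drop=True)
        d5 = regressions._raw_columns(df, 5)[0].reset_index(drop=True)
        d6 = regressions._raw_columns(df, 6)[0].reset_index(drop=True)
        for i, t in enumerate(range(1, 9)):
            R = int(odors[t] == odors[t - 1])
            W = int(rewards[t - 1] == 1)
            assert d2.loc[i, "repeat"] == R
            assert d2.loc[i, "repeat_reward"] == (0 if R == 0 else (1 if W else -1))
            assert d2.loc[i, "norepeat_reward"] == (0 if R == 1 else (1 if W else -1))
            assert d4.loc[i, "repeat_reward"] == R * W
            assert d4.loc[i, "repeat_noreward"] == R * (1 - W)
            assert d4.loc[i, "norepeat_reward"] == (1 - R) * W
            assert d4.loc[i, "norepeat_noreward"] == (1 - R) * (1 - W)
            assert d5.loc[i, "reward_x_repeat"] == R * W
            assert d6.loc[i, "repeat_reward"] == (0 if R == 0 else (1 if W else -1))

        d1 = regressions._raw_columns(df, 1)[0].reset_index(drop=True)
        for i, t in enumerate(range(2, 9)):
            assert d1.loc[i, "one_back"] == int(odors[t] == odors[t - 1])
            assert d1.loc[i, "two_back"] == int(odors[t] == odors[t - 2])

    def test_four_trial_toy_from_hand_enumeration(self):
        # odors X,X,Y,X with rewards 1,0,1,1
        df = make_session(["X", "X", "Y", "X"], ["L", "R", "R", "L"], {"X": "L", "Y": "R"})
        raw, idx = regressions._raw_columns(df, 3)
        assert list(idx) == [1, 2, 3]
        # trial 2: prev rewarded + repeat
        assert raw.loc[0, "reward"] == 1 and raw.loc[0, "reward_repeat"] == 1
        assert raw.loc[0, "noreward_repeat"] == 0
        # trial 3: prev unrewarded, stimulus changed
        assert raw.loc[1, "reward"] == 0 and raw.loc[1, "noreward_repeat"] == -1
        assert raw.loc[1, "reward_repeat"] == 0
        # trial 4: prev rewarded, stimulus changed; one past correct X choice
        assert raw.loc[2, "reward"] == 1 and raw.loc[2, "reward_repeat"] == -1
        assert raw.loc[2, "correct_history"] == pytest.approx(np.log1p(1))

    def test_history_dropping(self):
        df = _simulated(30)
        assert build_design(df, 3).included_trials[0] == 1
        assert build_design(df, 1).included_trials[0] == 2

    def test_zscoring_is_exact(self):
        df = _simulated(31)
        for rid in (1, 2, 3, 5):
            X = build_design(df, rid).X
            np.testing.assert_allclose(X.mean(), 0, atol=1e-10)
            np.testing.assert_allclose(X.std(ddof=0), 1, atol=1e-10)

    def test_constant_column_raises_named_error(self):
        # single odor: every trial repeats, the repeat column has no variance
        odors = ["X"] * 40
        choices = ["L" if i % 3 else "R" for i in range(40)]
        df = make_session(odors, choices, {"X": "L"})
        with pytest.raises(DegenerateDesignError, match="one_back|repeat"):
            build_design(df, 1)

    def test_too_few_trials_flagged_empty(self):
        df = make_session(["X", "Y"] * 4, ["L"] * 8, {"X": "L", "Y": "R"})
        d = build_design(df, 3)
        assert d.flagged and d.n == 0

    def test_rank_deficiency_detected_for_cell_and_redundant_designs(self):
        df = _simulated(32)
        assert build_design(df, 4).rank_deficient
        assert build_design(df, 6).rank_deficient
        assert not build_design(df, 3).rank_deficient


class TestLogisticFit:
    def test_equivalent_designs_reach_equal_likelihood(self):
        for seed in (40, 41, 42):
            df = _simulated(seed)
            r2 = fit_logistic(build_design(df, 2))
            r3 = fit_logistic(build_design(df, 3))
            assert r2.negll == pytest.approx(r3.negll, abs=1e-8)
            assert r2.aic == pytest.approx(r3.aic, abs=1e-6)

    def test_null_outcome_gives_small_coefficients(self):
        rng = np.random.default_rng(50)
        est = []
        for i in range(20):
            df = random_session(rng, n_trials=200, session_id=f"n{i}")
            res = fit_logistic(build_design(df, 3))
            est.append(res.coef.drop("intercept"))
        mean_abs = pd.concat(est, axis=1).mean(axis=1).abs()
        assert (mean_abs < 0.12).all()

    def test_win_stay_agent_shows_positive_reward_repeat_weight(self):
        p = dict(WINNING_PARAMS, s2=1.2, s4=1.2, s1=0.0, s3=0.0)
        coefs = []
        for i in range(8):
            df = _simulated(60 + 3 * i, params=p)
            coefs.append(fit_logistic(build_design(df, 3)).coef["reward_repeat"])
        assert np.mean(coefs) > 0.1

    def test_separation_triggers_flagged_ridge_refit(self):
        # outcome exactly equals the repeat indicator: perfect separation
        sched = task.build_schedule(task.SessionSpec(2, 40, seed=77))
        odors = list(sched.odor_ids)
        sides = sched.correct_side
        choices = []
        for t, o in enumerate(odors):
            correct = t > 0 and o == odors[t - 1]
            choices.append(sides[o] if correct else ("R" if sides[o] == "L" else "L"))
        df = make_session(odors, choices, sides)
        res = fit_logistic(build_design(df, 2))
        assert res.separated and not res.converged
        assert np.isfinite(res.negll)

    def test_estimator_wrapper(self):
        df = _simulated(70)
        est = TrialHistoryLogit(regression_id=3).fit(df)
        assert est.coef_.index[0] == "intercept"
        assert est.aic_ == pytest.approx(2 * est.negll_ + 2 * est.result_.k)
        assert est.result_.aicc > est.aic_
        assert est.result_.caic > est.result_.bic


class TestCorrelationsAndComparison:
    def test_duplicate_and_orthogonal_columns(self):
        d = build_design(_simulated(80), 3)
        corr = regressor_correlations(d)
        assert corr.loc["reward", "reward"] == pytest.approx(1.0)
        n = 400
        X = pd.DataFrame({"a": np.tile([1.0, -1.0], n // 2), "b": np.repeat([1.0, -1.0], n // 2)})
        d.X = (X - X.mean()) / X.std(ddof=0)
        corr2 = regressor_correlations(d)
        assert corr2.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)
        res_vif = regressions._vif(d.X)
        assert res_vif["a"] == pytest.approx(1.0) and res_vif["b"] == pytest.approx(1.0)

    def test_reward_and_reward_repeat_share_one_back_information(self):
        # the pair draws on the same previous-trial reward, so it is among
        # the most strongly correlated regressor pairs; the sign depends on
        # the schedule's repeat fraction (negative under block schedules,
        # where repeats are rarer than non-repeats)
        vals = [
            regressor_correlations(build_design(_simulated(90 + i), 3)).loc[
                "reward", "reward_repeat"
            ]
            for i in range(5)
        ]
        assert np.mean(np.abs(vals)) > 0.3

    def test_comparison_table_mean_arithmetic_and_equivalence_tie(self, small_cohort):
        comp = compare_regressions(small_cohort, regression_ids=(2, 3))
        assert comp.loc[2, "aic"] == pytest.approx(comp.loc[3, "aic"], abs=1e-5)
        _, crit = fit_sessions(small_cohort, (3,))
        assert comp.loc[3, "bic"] == pytest.approx(crit["bic"].mean())

    def test_outlier_filter_drops_extreme_sessions_only(self):
        base = pd.DataFrame(
            {
                "session_id": [f"s{i}" for i in range(20)],
                "regression_id": 3,
                "term": "reward",
                "estimate": [0.1] * 19 + [50.0],
            }
        )
        kept = drop_coefficient_outliers(base)
        assert len(kept) == 19 and 50.0 not in kept["estimate"].values
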