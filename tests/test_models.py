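"""Model registry, value updates, policy, and the session likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rlstrat import models

from conftest import make_session, oracle_negll, random_full_params, random_session

NOS = {k: 0.0 for k in models.PARAM_NAMES}


class TestRegistry:
    def test_winning_model_partition(self):
        spec = models.get_model("a0bs1232")
        assert set(spec.free) == {"alpha_plus", "beta", "s1", "s2", "s3"}
        assert spec.fixed["alpha_minus"] == 0.0
        assert spec.ties == {"s4": "s2"}
        assert spec.n_free == 5

    @pytest.mark.parametrize("name", models.REGISTRY_NAMES)
    def test_name_round_trip(self, name):
        assert models.model_name(models.parse_model(name)) == name

    @pytest.mark.parametrize(
        "name,free",
        [
            ("a0b-nos", {"alpha_plus", "beta"}),
            ("a0bs1", {"alpha_plus", "beta", "s1"}),
            ("a0bs13", {"alpha_plus", "beta", "s1", "s3"}),
            ("a0bs1234", {"alpha_plus", "beta", "s1", "s2", "s3", "s4"}),
            ("aabs1232", {"alpha_plus", "alpha_minus", "beta", "s1", "s2", "s3"}),
            ("a0bs1232-phi", {"alpha_plus", "beta", "phi", "s1", "s2", "s3"}),
        ],
    )
    def test_grammar(self, name, free):
        assert set(models.parse_model(name).free) == free

    @pytest.mark.parametrize("bad", ["xyz", "a0c", "a0bs5", "a0bs11", "a0b-nos-bad"])
    def test_unparseable_names_rejected(self, bad):
        with pytest.raises(models.ModelError):
            models.parse_model(bad)

    def test_resolve_applies_fixed_and_ties(self):
        spec = models.get_model("a0bs1232")
        full = spec.resolve([0.3, 4.0, 0.1, 0.5, 0.2])
        assert full["alpha_minus"] == 0.0 and full["s4"] == full["s2"] == 0.5


class TestValueUpdates:
    @pytest.mark.parametrize(
        "q,r,ap,am,expected",
        [
            (0.5, 1, 0.5, 0.0, 0.75),
            (0.5, 0, 0.7, 0.0, 0.5),  # alpha_minus = 0: no learning from errors
            (0.75, 1, 1.0, 0.0, 1.0),
            (0.8, 0, 0.1, 0.5, 0.4),
        ],
    )
    def test_delta_rule_arithmetic(self, q, r, ap, am, expected):
        p = dict(NOS, alpha_plus=ap, alpha_minus=am)
        assert models.update_value(q, r, p) == pytest.approx(expected)

    @pytest.mark.parametrize("phi,q,expected", [(0.5, 0.9, 0.7), (0.0, 0.9, 0.9), (1.0, 0.1, 0.5)])
    def test_forgetting_decay(self, phi, q, expected):
        table = np.array([[q, 0.5]])
        out = models.apply_forgetting(table, dict(NOS, phi=phi))
        assert out[0, 0] == pytest.approx(expected)
        assert table[0, 0] == q  # input untouched

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        alpha=st.floats(0, 1), q=st.floats(0, 1), rewards=st.lists(st.integers(0, 1), max_size=30)
    )
    def test_values_stay_in_unit_interval(self, alpha, q, rewards):
        p = dict(NOS, alpha_plus=alpha, alpha_minus=alpha)
        for r in rewards:
            q = models.update_value(q, r, p)
            assert 0.0 <= q <= 1.0


class TestTrialTypes:
    @pytest.mark.parametrize(
        "prev,cur,r,expected",
        [
            ("X", "Y", 0, models.T1),
            ("X", "Y", 1, models.T2),
            ("X", "X", 0, models.T3),
            ("X", "X", 1, models.T4),
        ],
    )
    def test_two_by_two(self, prev, cur, r, expected):
        assert models.classify_trial_type(prev, cur, r) == expected

    def test_lose_shift_bias_is_negative_on_repeat_action(self):
        b = models.effective_biases(dict(NOS, s1=0.4, s2=0.5, s3=0.6, s4=0.7))
        assert b == (-0.4, 0.5, 0.6, 0.7)


class TestChoiceProbabilities:
    def test_symmetry_without_bias(self):
        p = models.choice_probabilities([0.5, 0.5], models.NO_BIAS, None, dict(NOS, beta=7.0))
        assert p == pytest.approx([0.5, 0.5])

    def test_logistic_closed_form_with_repeat_bias(self):
        # equal values, beta=1, repeat bias +1 toward previous (left) choice
        params = dict(NOS, beta=1.0, s4=1.0)
        p = models.choice_probabilities([0.5, 0.5], models.T4, 0, params)
        assert p[0] == pytest.approx(1 / (1 + math.exp(-1)), abs=1e-12)

    def test_beta_zero_is_uniform_regardless_of_state(self):
        params = dict(NOS, beta=0.0, s2=3.0)
        p = models.choice_probabilities([0.9, 0.1], models.T2, 1, params)
        assert p == pytest.approx([0.5, 0.5])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        q0=st.floats(0, 1), q1=st.floats(0, 1), beta=st.floats(0, 50),
        s=st.floats(-5, 5), tt=st.integers(0, 4), prev=st.integers(0, 1),
    )
    def test_probabilities_sum_to_one(self, q0, q1, beta, s, tt, prev):
        params = dict(NOS, beta=beta, s1=s, s2=s, s3=s, s4=s)
        p = models.choice_probabilities([q0, q1], tt, None if tt == 0 else prev, params)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert (p > 0).all()


class TestSessionLikelihood:
    def test_hand_chained_two_trial_example(self):
        # same odor twice, both correct: -(ln 0.5 + ln sigmoid(0.25))
        df = make_session(["X", "X"], ["L", "L"], {"X": "L"})
        p = dict(NOS, alpha_plus=0.5, beta=1.0)
        expected = -(math.log(0.5) + math.log(1 / (1 + math.exp(-0.25))))
        assert models.negative_log_likelihood(df, p, "a0b-nos") == pytest.approx(
            expected, abs=1e-10
        )
        assert expected == pytest.approx(1.269086, abs=1e-6)

    def test_beta_zero_gives_n_log_two(self):
        rng = np.random.default_rng(0)
        df = random_session(rng, n_trials=37)
        assert models.negative_log_likelihood(df, NOS, "a0b-nos") == pytest.approx(
            37 * math.log(2), abs=1e-10
        )

    @pytest.mark.parametrize("name", models.REGISTRY_NAMES)
    def test_matches_bruteforce_trace_on_random_sessions(self, name):
        import zlib

        rng = np.random.default_rng(zlib.crc32(name.encode()) % 2**31)
        spec = models.get_model(name)
        for _ in range(20):
            df = random_session(rng, n_trials=10, n_odors=int(rng.integers(2, 5)))
            params = random_full_params(rng, spec)
            ours = models.negative_log_likelihood(df, params, spec)
            ref = oracle_negll(df, params)
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_zero_strategies_reduce_to_pure_rl(self):
        rng = np.random.default_rng(3)
        df = random_session(rng, n_trials=60)
        p = dict(NOS, alpha_plus=0.2, beta=3.0)
        full = models.negative_log_likelihood(df, p, "a0bs1234")
        pure = models.negative_log_likelihood(df, p, "a0b-nos")
        assert full == pytest.approx(pure, abs=1e-12)

    def test_generating_params_beat_wrong_params_on_average(self):
        from rlstrat import task

        gen = dict(NOS, alpha_plus=0.15, beta=5.0, s2=0.6, s4=0.6)
        wrong = dict(NOS, alpha_plus=0.9, beta=0.3)
        diffs = []
        for i in range(100):
            sched = task.build_schedule(task.SessionSpec(2, 40, seed=3000 + i))
            df = task.simulate_session(sched, gen, "a0bs1232", seed=i)
            diffs.append(
                models.negative_log_likelihood(df, wrong, "a0b-nos")
                - models.negative_log_likelihood(df, gen, "a0bs1232")
            )
        assert np.mean(diffs) > 0

    def test_multi_session_input_rejected(self):
        rng = np.random.default_rng(1)
        a = random_session(rng, session_id="a")
        b = random_session(rng, session_id="b")
        import pandas as pd

        with pytest.raises(Exception):
            models.negative_log_likelihood(pd.concat([a, b]), NOS, "a0b-nos")
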