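import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from revlearn import cohort, models, task
from revlearn.models import (
    MODELS, ParameterError, belief_trajectory, dsa_update, get_model,
    hmm_action_prob, hmm_observe, hmm_transition, log_likelihood, make_agent,
    q_action_prob, sa_update, simulate_agent,
)
from tests.conftest import trials_frame
from tests.oracles import enumerate_choice_probability_mass, path_enumeration_beliefs


def random_params(spec, rng):
    out = {}
    for name, tr in zip(spec.parameter_names, spec.transforms):
        if tr == "logit":
            out[name] = float(rng.uniform(0.05, 0.95))
        else:
            out[name] = float(np.exp(rng.normal(0.3, 0.6)))
    return out


class TestRegistry:
    def test_six_models(self):
        assert sorted(MODELS) == ["DSA", "DSA-RP", "HMM", "HMM-RP", "SA", "SA-RP"]

    @pytest.mark.parametrize("name,k", [
        ("SA", 2), ("DSA", 2), ("HMM", 2), ("SA-RP", 3), ("DSA-RP", 3), ("HMM-RP", 3),
    ])
    def test_parameter_counts(self, name, k):
        assert get_model(name).n_params == k

    def test_unknown_model(self):
        with pytest.raises(KeyError, match="unknown model"):
            get_model("WSLS")


class TestQUpdates:
    def test_sa_reward_from_zero(self):
        q = sa_update(np.zeros(2), 0, +1.0, eps=0.5)
        assert q[0] == pytest.approx(0.5) and q[1] == 0.0

    def test_sa_zero_learning_rate(self):
        q0 = np.array([0.3, -0.2])
        assert np.allclose(sa_update(q0, 1, +1.0, eps=0.0), q0)

    def test_sa_punishment(self):
        q = sa_update(np.array([0.5, 0.0]), 0, -1.0, eps=0.5)
        assert q[0] == pytest.approx(-0.25)

    def test_sa_unchosen_untouched(self, rng):
        q = np.array([0.1, -0.4])
        q2 = sa_update(q, 0, 1.0, eps=0.3)
        assert q2[1] == q[1]

    def test_dsa_reward_antisymmetric_step(self):
        q = dsa_update(np.zeros(2), 0, +1.0, eps=0.5)
        assert q[0] == pytest.approx(0.5) and q[1] == pytest.approx(-0.5)

    def test_dsa_punishment(self):
        q = dsa_update(np.zeros(2), 0, -1.0, eps=0.5)
        assert q[0] == pytest.approx(-0.5) and q[1] == pytest.approx(0.5)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 1), st.sampled_from([1.0, -1.0])),
                    min_size=1, max_size=30),
           st.floats(0.05, 0.95))
    def test_dsa_antisymmetry_property(self, seq, eps):
        q = np.zeros(2)
        for choice, r in seq:
            q = dsa_update(q, choice, r, eps)
        assert q[0] == pytest.approx(-q[1], abs=1e-12)

    def test_q_bounded_by_sensitivity(self, rng):
        q = np.zeros(2)
        for _ in range(200):
            q = dsa_update(q, int(rng.integers(2)),
                           float(rng.choice([2.0, -1.5])), 0.7)
        assert np.max(np.abs(q)) <= 2.0 + 1e-12

    def test_bad_learning_rate(self):
        with pytest.raises(ParameterError):
            sa_update(np.zeros(2), 0, 1.0, eps=1.5)


class TestChoiceRules:
    def test_symmetric_q_gives_even_odds(self):
        assert np.allclose(q_action_prob(np.zeros(2)), [0.5, 0.5])

    def test_shift_invariance(self):
        p1 = q_action_prob(np.array([0.2, -0.1]))
        p2 = q_action_prob(np.array([0.2 + 3.0, -0.1 + 3.0]))
        assert np.allclose(p1, p2)

    def test_large_difference_saturates(self):
        p = q_action_prob(np.array([5.0, -5.0]))
        assert p[0] == pytest.approx(1.0, abs=1e-4)
        assert p.sum() == pytest.approx(1.0)

    def test_belief_probability_matching(self):
        assert np.allclose(hmm_action_prob(0.5), [0.5, 0.5])
        assert np.allclose(hmm_action_prob(1.0), [1.0, 0.0])
        assert np.allclose(hmm_action_prob(0.8), [0.8, 0.2])


class TestBeliefUpdates:
    def test_transition_fixed_point(self):
        for gamma in (0.1, 0.5, 0.9):
            assert hmm_transition(0.5, gamma) == pytest.approx(0.5)

    def test_full_mixing(self):
        for b in (0.0, 0.3, 1.0):
            assert hmm_transition(b, 0.5) == pytest.approx(0.5)

    def test_two_state_algebra(self):
        assert hmm_transition(0.9, 0.9) == pytest.approx(0.82)

    def test_unit_sensitivity_is_exact_bayes(self):
        b = hmm_observe(0.5, 0, "reward", gamma=0.9, c_rew=1.0, c_pun=1.0)
        assert b == pytest.approx(0.8)

    def test_zero_reward_sensitivity_freezes_belief(self):
        b = hmm_observe(0.37, 1, "reward", gamma=0.9, c_rew=0.0, c_pun=1.0)
        assert b == pytest.approx(0.37)

    def test_evidence_cancellation(self):
        b0 = 0.62
        b1 = hmm_observe(b0, 0, "reward", 1.0, 1.0, 1.0)
        b2 = hmm_observe(b1, 0, "punishment", 1.0, 1.0, 1.0)
        assert b2 == pytest.approx(b0)


class TestLogLikelihood:
    def test_empty_sequence(self):
        df = trials_frame([], [])
        ll, p = log_likelihood(MODELS["SA"], {"epsilon": 0.3, "rho": 1.0}, df)
        assert ll == 0.0 and len(p) == 0

    def test_zero_sensitivity_uniform_policy(self):
        df = trials_frame([0, 1, 0, 1, 1], [1, 0, 1, 1, 0])
        ll, p = log_likelihood(MODELS["SA"], {"epsilon": 0.3, "rho": 0.0}, df)
        assert ll == pytest.approx(5 * np.log(0.5))
        assert np.allclose(p, 0.5)

    def test_invalid_trials_skipped(self):
        df = trials_frame([0, 1, 0], [1, 0, 1], valid=[True, False, True])
        ll, p = log_likelihood(MODELS["HMM"], {"gamma": 0.9, "c": 1.0}, df)
        assert np.isnan(p[1]) and np.isfinite(ll)

    def test_session_reset(self):
        # identical single-trial sessions must get identical first-trial odds
        df = trials_frame([0, 0], [1, 1], session=[0, 1])
        _, p = log_likelihood(MODELS["HMM"], {"gamma": 0.9, "c": 2.0}, df)
        assert p[0] == pytest.approx(p[1])

    @pytest.mark.parametrize("name", sorted(MODELS))
    def test_normalization_by_enumeration(self, name, rng):
        spec = MODELS[name]
        outcome_table = rng.integers(0, 2, (6, 2))
        params = random_params(spec, rng)
        total = enumerate_choice_probability_mass(spec, params, outcome_table,
                                                  log_likelihood)
        assert total == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("name", sorted(MODELS))
    def test_left_right_relabeling_symmetry(self, name, rng):
        spec = MODELS[name]
        params = random_params(spec, rng)
        cfg = task.TaskConfig(n_sessions=1, trials_per_session=60)
        df = simulate_agent(spec, params, cfg, seed=11)
        mirrored = df.copy()
        mirrored["choice"] = df["choice"].map({"left": "right", "right": "left"})
        mirrored["block_type"] = df["block_type"].map(
            {"right_better": "left_better", "left_better": "right_better",
             "neutral": "neutral"})
        ll, _ = log_likelihood(spec, params, df)
        ll_m, _ = log_likelihood(spec, params, mirrored)
        assert ll == pytest.approx(ll_m, abs=1e-9)

    def test_out_of_domain_params(self):
        df = trials_frame([0, 1], [1, 0])
        with pytest.raises(ParameterError):
            log_likelihood(MODELS["HMM"], {"gamma": 1.7, "c": 1.0}, df)
        with pytest.raises(ParameterError):
            log_likelihood(MODELS["SA"], {"epsilon": 0.5, "rho": -1.0}, df)

    @pytest.mark.parametrize("name", sorted(MODELS))
    def test_choice_probabilities_interior(self, name, rng):
        spec = MODELS[name]
        params = random_params(spec, rng)
        df = simulate_agent(spec, params, task.TaskConfig(n_sessions=1), seed=2)
        _, p = log_likelihood(spec, params, df)
        assert np.all((p > 0) & (p < 1))


class TestBeliefFilterOracle:
    @pytest.mark.parametrize("gamma", [0.6, 0.85, 0.95])
    def test_matches_path_enumeration(self, gamma, rng):
        T = 10
        choices = rng.integers(0, 2, T)
        outcomes = rng.integers(0, 2, T)
        df = trials_frame(choices, outcomes)
        traj = belief_trajectory({"gamma": gamma, "c": 1.0}, df)
        b_prior, b_post = path_enumeration_beliefs(choices, outcomes, gamma)
        np.testing.assert_allclose(traj["b_prior"], b_prior, atol=1e-10)
        np.testing.assert_allclose(traj["b_post"], b_post, atol=1e-10)

    def test_beliefs_stay_in_unit_interval(self, rng):
        df = trials_frame(rng.integers(0, 2, 50), rng.integers(0, 2, 50))
        traj = belief_trajectory({"gamma": 0.97, "c_rew": 4.0, "c_pun": 0.5}, df)
        assert traj.to_numpy().min() >= 0.0 and traj.to_numpy().max() <= 1.0

    def test_rejects_q_models(self):
        df = trials_frame([0], [1])
        with pytest.raises(ValueError, match="HMM"):
            belief_trajectory({"epsilon": 0.1, "rho": 1.0}, df, MODELS["SA"])


class TestSimulateAgent:
    def test_determinism(self):
        spec = MODELS["HMM"]
        params = {"gamma": 0.9, "c": 2.0}
        cfg = task.TaskConfig()
        a = simulate_agent(spec, params, cfg, seed=9)
        b = simulate_agent(spec, params, cfg, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_insensitive_agent_flat_at_chance(self):
        spec = MODELS["HMM-RP"]
        params = {"gamma": 0.9, "c_rew": 0.0, "c_pun": 0.0}
        dfs = [simulate_agent(spec, params, task.TaskConfig(n_sessions=1), seed=s,
                              subject_id=f"s{s}") for s in range(40)]
        df = pd.concat(dfs, ignore_index=True)
        pc = cohort.percent_correct(df)
        assert abs(pc - 50.0) < 5.0

    def test_good_agent_recovers_after_reversal(self):
        spec = MODELS["HMM"]
        params = {"gamma": 0.95, "c": 3.0}
        dfs = [simulate_agent(spec, params, task.TaskConfig(n_sessions=1), seed=s,
                              subject_id=f"s{s:03d}") for s in range(100)]
        summary = cohort.learning_curves(pd.concat(dfs, ignore_index=True))
        curve = summary.curves.mean(axis=0)
        assert curve[1] < 0.5  # still choosing the previously good side
        assert curve.iloc[1:].max() > 0.7  # adapted within ten trials
        assert curve.iloc[-3:].mean() > curve[1]

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            make_agent(MODELS["SA"], {"epsilon": -0.1, "rho": 1.0})
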