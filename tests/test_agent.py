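"""Hybrid learner: value computation, choice rule, updates, simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twostep_social import (
    AgentParameters,
    TaskConfig,
    ValueState,
    choice_probabilities,
    mb_values,
    simulate_agent,
    update_values,
)
from twostep_social.task import TrialRecord, transition


def make_vs(q_mf, q_stage2):
    return ValueState(q_mf=np.array(q_mf, dtype=float), q_stage2=np.array(q_stage2, dtype=float))


class TestModelBasedValues:
    def test_advisors_sharing_a_stock_share_mb_value(self, config):
        vs = make_vs([[0, 0], [0, 0]], [6.0, 1.0])
        q = mb_values(vs, config)
        for s in range(2):
            for a in range(2):
                assert q[s, a] == vs.q_stage2[transition(s, a, config)]
        # each stock's value appears once per start state
        assert sorted(q[0]) == sorted(q[1]) == [1.0, 6.0]

    def test_zero_stage2_values_give_zero_mb(self, config):
        q = mb_values(make_vs([[9, 9], [9, 9]], [0.0, 0.0]), config)
        assert np.all(q == 0.0)

    def test_lookup_matches_transition_table(self):
        tm = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 0}
        cfg = TaskConfig(transition_map=tm)
        q = mb_values(make_vs([[0, 0], [0, 0]], [3.0, 5.0]), cfg)
        assert list(q[0]) == [3.0, 5.0]
        assert list(q[1]) == [5.0, 3.0]


class TestChoiceProbabilities:
    def test_flat_policy_at_zero_beta(self, config):
        p = AgentParameters(alpha=0.3, beta=0.0, lam=0.5, w=0.5, pi=0.0)
        vs = make_vs([[7, 1], [2, 2]], [9.0, 0.0])
        probs = choice_probabilities(vs, p, 0, None, config)
        assert probs == pytest.approx([0.5, 0.5])

    def test_symmetric_values_give_even_odds(self, config):
        p = AgentParameters(alpha=0.3, beta=2.0, lam=0.5, w=0.5, pi=0.0)
        vs = make_vs([[4, 4], [4, 4]], [4.0, 4.0])
        probs = choice_probabilities(vs, p, 1, None, config)
        assert probs == pytest.approx([0.5, 0.5])

    def test_hand_computed_softmax(self, config):
        # V = 0.5*(5,3) + 0.5*(4,2) = (4.5, 2.5); P0 = 1/(1+e^-2)
        p = AgentParameters(alpha=0.5, beta=1.0, lam=0.5, w=0.5, pi=0.0)
        vs = make_vs([[4, 2], [0, 0]], [5.0, 3.0])
        probs = choice_probabilities(vs, p, 0, None, config)
        assert probs[0] == pytest.approx(1.0 / (1.0 + math.exp(-2.0)), abs=1e-12)

    def test_perseveration_bonus_applies_to_previous_slot(self, config):
        p = AgentParameters(alpha=0.5, beta=1.0, lam=0.5, w=0.5, pi=0.8)
        vs = make_vs([[4, 4], [4, 4]], [4.0, 4.0])
        probs = choice_probabilities(vs, p, 0, 1, config)
        assert probs[1] == pytest.approx(1.0 / (1.0 + math.exp(-0.8)), abs=1e-12)

    def test_no_overflow_at_extreme_beta(self, config):
        p = AgentParameters(alpha=0.5, beta=1e6, lam=0.5, w=0.5, pi=0.0)
        vs = make_vs([[9, 0], [0, 0]], [9.0, 0.0])
        probs = choice_probabilities(vs, p, 0, None, config)
        assert np.isfinite(probs).all()
        assert probs[0] == pytest.approx(1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        q=st.lists(st.floats(-10, 10), min_size=6, max_size=6),
        beta=st.floats(0, 20),
        w=st.floats(0, 1),
        pi=st.floats(-3, 3),
        state=st.integers(0, 1),
        prev=st.sampled_from([None, 0, 1]),
    )
    def test_probabilities_sum_to_one(self, q, beta, w, pi, state, prev):
        cfg = TaskConfig()
        p = AgentParameters(alpha=0.5, beta=beta, lam=0.5, w=w, pi=pi)
        vs = make_vs([q[0:2], q[2:4]], q[4:6])
        probs = choice_probabilities(vs, p, state, prev, cfg)
        assert abs(probs.sum() - 1.0) < 1e-12

    def test_monotone_in_own_value(self, config):
        p = AgentParameters(alpha=0.5, beta=1.0, lam=0.5, w=0.0, pi=0.0)
        last = 0.0
        for v in np.linspace(0, 9, 10):
            vs = make_vs([[v, 4.0], [0, 0]], [0.0, 0.0])
            prob = choice_probabilities(vs, p, 0, None, config)[0]
            assert prob >= last
            last = prob

    def test_fully_model_based_policy_ignores_mf_values(self, config):
        p = AgentParameters(alpha=0.5, beta=1.3, lam=0.5, w=1.0, pi=0.2)
        a = make_vs([[1, 8], [3, 3]], [5.0, 2.0])
        b = make_vs([[6, 0], [9, 1]], [5.0, 2.0])
        pa = choice_probabilities(a, p, 0, 1, config)
        pb = choice_probabilities(b, p, 0, 1, config)
        assert pa == pytest.approx(pb, abs=1e-14)

    def test_fully_model_free_policy_ignores_stage2_values(self, config):
        p = AgentParameters(alpha=0.5, beta=1.3, lam=0.5, w=0.0, pi=0.2)
        a = make_vs([[1, 8], [3, 3]], [5.0, 2.0])
        b = make_vs([[1, 8], [3, 3]], [0.0, 9.0])
        pa = choice_probabilities(a, p, 1, 0, config)
        pb = choice_probabilities(b, p, 1, 0, config)
        assert pa == pytest.approx(pb, abs=1e-14)


class TestValueUpdates:
    def make_trial(self, config, s=0, a=0, r=7.0):
        k = transition(s, a, config)
        return TrialRecord(
            subject_id="s0", trial=0, start_state=s, choice=a,
            advisor_id=2 * s + a, stock=k, reward=r, missed=False,
        )

    def test_stage2_moves_halfway_at_half_learning_rate(self, config):
        p = AgentParameters(alpha=0.5, beta=1.0, lam=0.0, w=0.5, pi=0.0)
        vs = make_vs([[2, 2], [2, 2]], [3.0, 3.0])
        out = update_values(vs, self.make_trial(config, r=7.0), p)
        assert out.q_stage2[0] == pytest.approx(5.0)

    def test_zero_learning_rate_changes_nothing(self, config):
        p = AgentParameters(alpha=0.0, beta=1.0, lam=1.0, w=0.5, pi=0.0)
        vs = make_vs([[2, 5], [1, 4]], [3.0, 8.0])
        out = update_values(vs, self.make_trial(config, r=7.0), p)
        assert np.array_equal(out.q_mf, vs.q_mf)
        assert np.array_equal(out.q_stage2, vs.q_stage2)

    def test_two_step_update_with_full_trace(self, config):
        # q_mf 2, q2 3, r 7, alpha .5, lam 1:
        # delta1 = 1 -> q_mf 2.5; delta2 = 4 -> q_mf += .5*4 = 4.5
        p = AgentParameters(alpha=0.5, beta=1.0, lam=1.0, w=0.5, pi=0.0)
        vs = make_vs([[2, 0], [0, 0]], [3.0, 0.0])
        out = update_values(vs, self.make_trial(config, r=7.0), p)
        assert out.q_mf[0, 0] == pytest.approx(4.5)
        assert out.q_stage2[0] == pytest.approx(5.0)

    def test_only_visited_cells_change(self, config):
        p = AgentParameters(alpha=0.5, beta=1.0, lam=0.7, w=0.5, pi=0.0)
        vs = make_vs([[2, 5], [1, 4]], [3.0, 8.0])
        out = update_values(vs, self.make_trial(config, s=0, a=0, r=7.0), p)
        assert out.q_mf[0, 1] == vs.q_mf[0, 1]
        assert np.array_equal(out.q_mf[1], vs.q_mf[1])
        k_other = 1 - transition(0, 0, config)
        assert out.q_stage2[k_other] == vs.q_stage2[k_other]

    def test_missed_trial_is_a_no_op(self, config):
        p = AgentParameters(alpha=0.9, beta=1.0, lam=1.0, w=0.5, pi=0.0)
        vs = make_vs([[2, 5], [1, 4]], [3.0, 8.0])
        trial = TrialRecord(
            subject_id="s0", trial=0, start_state=0, choice=None,
            advisor_id=None, stock=None, reward=None, missed=True,
        )
        out = update_values(vs, trial, p)
        assert np.array_equal(out.q_mf, vs.q_mf)
        assert np.array_equal(out.q_stage2, vs.q_stage2)


class TestSimulateAgent:
    def test_full_session_shape_and_consistency(self, config, example_session):
        assert len(example_session) == config.n_trials
        for rec in example_session:
            assert rec.stock == transition(rec.start_state, rec.choice, config)
            assert rec.advisor_id == 2 * rec.start_state + rec.choice
            assert 0 <= rec.reward <= 9 and rec.reward == int(rec.reward)

    def test_flat_policy_chooses_both_slots_evenly(self, config):
        p = AgentParameters(alpha=0.5, beta=0.0, lam=0.5, w=0.5, pi=0.0)
        rng = np.random.default_rng(5)
        choices = []
        for _ in range(20):
            choices.extend(r.choice for r in simulate_agent(p, config, rng))
        freq = np.mean(choices)
        assert abs(freq - 0.5) < 3 * 0.5 / np.sqrt(len(choices))

    def test_same_seed_bitwise_identical(self, config, default_params):
        a = simulate_agent(default_params, config, np.random.default_rng(9))
        b = simulate_agent(default_params, config, np.random.default_rng(9))
        assert a == b

    def test_miss_mask_produces_blank_trials(self, config, default_params):
        mask = np.zeros(config.n_trials, dtype=bool)
        mask[[3, 70, 149]] = True
        session = simulate_agent(
            default_params, config, np.random.default_rng(2), miss_mask=mask
        )
        for t in (3, 70, 149):
            assert session[t].missed and session[t].reward is None
        assert sum(r.missed for r in session) == 3


class TestSequenceEnumeration:
    """Chained one-step probabilities must reproduce the generative tree.

    For a 3-trial session with fixed start states and a fixed reward
    schedule, the probability of each of the 8 choice sequences computed by
    chaining choice_probabilities (with value updates in between) must form
    a probability distribution, and each leaf's probability must equal an
    independent hand-rolled computation of the same generative process.
    """

    PARAMS = AgentParameters(alpha=0.6, beta=1.2, lam=0.3, w=0.4, pi=0.25)
    STATES = [0, 1, 0]
    REWARDS = {0: [7.0, 6.0, 2.0], 1: [1.0, 3.0, 8.0]}  # stock -> per-trial payout

    def leaf_probability_package(self, choices, config):
        vs = ValueState.initial(config)
        prev = None
        prob = 1.0
        for t, (s, a) in enumerate(zip(self.STATES, choices)):
            probs = choice_probabilities(vs, self.PARAMS, s, prev, config)
            prob *= probs[a]
            k = transition(s, a, config)
            trial = TrialRecord(
                subject_id="x", trial=t, start_state=s, choice=a,
                advisor_id=2 * s + a, stock=k, reward=self.REWARDS[k][t],
                missed=False,
            )
            vs = update_values(vs, trial, self.PARAMS)
            prev = a
        return prob

    def leaf_probability_oracle(self, choices, config):
        # independent scalar reimplementation of the same model
        al, be, lam, w, pi = 0.6, 1.2, 0.3, 0.4, 0.25
        q_mf = {(s, a): 4.5 for s in range(2) for a in range(2)}
        q2 = {0: 4.5, 1: 4.5}
        tm = config.transition_map
        prev = None
        prob = 1.0
        for t, (s, a) in enumerate(zip(self.STATES, choices)):
            vals = {}
            for slot in range(2):
                v = w * q2[tm[(s, slot)]] + (1 - w) * q_mf[(s, slot)]
                vals[slot] = be * v + (pi if slot == prev else 0.0)
            denom = math.exp(vals[0]) + math.exp(vals[1])
            prob *= math.exp(vals[a]) / denom
            k = tm[(s, a)]
            r = self.REWARDS[k][t]
            d1 = q2[k] - q_mf[(s, a)]
            q_mf[(s, a)] += al * d1
            d2 = r - q2[k]
            q2[k] += al * d2
            q_mf[(s, a)] += al * lam * d2
            prev = a
        return prob

    def test_eight_leaves_sum_to_one_and_match_oracle(self, config):
        total = 0.0
        for c0 in range(2):
            for c1 in range(2):
                for c2 in range(2):
                    leaf = self.leaf_probability_package((c0, c1, c2), config)
                    oracle = self.leaf_probability_oracle((c0, c1, c2), config)
                    assert leaf == pytest.approx(oracle, abs=1e-12)
                    total += leaf
        assert total == pytest.approx(1.0, abs=1e-12)
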