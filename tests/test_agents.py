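"""Learning rule, softmax choice, and bandit execution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evobandit import (
    RISKY,
    SAFE,
    Genome,
    TaskSpec,
    choice_probability,
    run_bandit_task,
    run_bandit_tasks,
    simulate_population,
    spawn_agent_rngs,
    update_value_asymmetric,
    update_value_single,
)

finite_rewards = st.floats(-100.0, 100.0)
rates = st.floats(0.0, 1.0)


class TestChoiceProbability:
    def test_equal_values_give_half(self):
        assert choice_probability([3.0, 3.0], 0.4) == 0.5

    def test_zero_beta_is_uniform(self):
        assert choice_probability([50.0, -10.0], 0.0) == 0.5

    def test_direct_evaluation(self):
        assert choice_probability([10.0, 0.0], 0.25) == pytest.approx(
            1.0 / (1.0 + np.exp(-2.5))
        )
        assert choice_probability([10.0, 0.0], 0.25) == pytest.approx(0.9241418, abs=1e-6)

    def test_extreme_arguments_saturate_without_error(self):
        assert choice_probability([1e308, -1e308], 0.5) == 1.0
        assert choice_probability([-1e308, 1e308], 0.5) == 0.0

    @given(v1=finite_rewards, v2=finite_rewards, beta=st.floats(0.0, 0.5))
    @settings(max_examples=100, derandomize=True)
    def test_two_option_probabilities_sum_to_one(self, v1, v2, beta):
        p_risky = choice_probability([v1, v2], beta)
        p_safe = choice_probability([v2, v1], beta)
        assert abs(p_risky + p_safe - 1.0) < 1e-12

    def test_monotone_in_value_difference_and_beta(self):
        diffs = np.linspace(-20, 20, 41)
        probs = [choice_probability([d, 0.0], 0.25) for d in diffs]
        assert np.all(np.diff(probs) > 0)
        betas = np.linspace(0.01, 0.5, 20)
        probs = [choice_probability([5.0, 0.0], b) for b in betas]
        assert np.all(np.diff(probs) > 0)


class TestValueUpdates:
    def test_positive_error_uses_positive_rate(self):
        V = update_value_asymmetric([0.0, 0.0], RISKY, 10.0, 0.5, 0.9)
        assert V[RISKY] == 5.0 and V[SAFE] == 0.0

    def test_negative_error_uses_negative_rate(self):
        V = update_value_asymmetric([0.0, 10.0], SAFE, 0.0, 0.5, 0.9)
        assert V[SAFE] == pytest.approx(1.0)
        assert V[RISKY] == 0.0

    def test_zero_error_leaves_value_unchanged(self):
        V = update_value_asymmetric([4.0, 0.0], RISKY, 4.0, 0.7, 0.2)
        assert V[RISKY] == 4.0

    @given(v=finite_rewards, reward=finite_rewards, alpha=rates)
    @settings(max_examples=100, derandomize=True)
    def test_single_rate_is_asymmetric_with_equal_rates(self, v, reward, alpha):
        a = update_value_single([v, 0.0], RISKY, reward, alpha)
        b = update_value_asymmetric([v, 0.0], RISKY, reward, alpha, alpha)
        assert a[RISKY] == b[RISKY]

    @given(v=finite_rewards, reward=finite_rewards, ap=rates, an=rates)
    @settings(max_examples=100, derandomize=True)
    def test_updated_value_lies_between_old_value_and_reward(self, v, reward, ap, an):
        new = update_value_asymmetric([v, 0.0], RISKY, reward, ap, an)[RISKY]
        low, high = min(v, reward), max(v, reward)
        assert low - 1e-9 <= new <= high + 1e-9

    def test_out_of_range_rates_rejected(self):
        with pytest.raises(ValueError):
            update_value_asymmetric([0.0, 0.0], RISKY, 1.0, 1.5, 0.5)


class TestGenome:
    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            Genome(1.2, 0.5, 0.25)
        with pytest.raises(ValueError):
            Genome(0.5, 0.5, 0.6)

    def test_single_rate_carries_one_learning_rate(self):
        g = Genome.single_rate(0.3, 0.2)
        assert g.alpha == 0.3 and g.alpha_p == g.alpha_n
        with pytest.raises(ValueError):
            Genome(0.3, 0.4, 0.2, variant="single_rate")


class TestRunBanditTask:
    def test_record_lengths_match_trials(self, risk_aversion_task, rng):
        rec = run_bandit_task(Genome(0.4, 0.4, 0.25), risk_aversion_task, 500, rng)
        assert rec.n_trials == 500
        assert rec.choices.size == rec.rewards.size == 500

    def test_deterministic_under_fixed_seed(self, risk_aversion_task):
        g = Genome(0.4, 0.6, 0.25)
        a = run_bandit_task(g, risk_aversion_task, 200, np.random.default_rng(3))
        b = run_bandit_task(g, risk_aversion_task, 200, np.random.default_rng(3))
        assert np.array_equal(a.choices, b.choices)
        assert np.array_equal(a.rewards, b.rewards)

    def test_greedy_agent_converges_to_dominant_safe_option(self):
        # safe mean far above risky, tiny spread, maximal beta: late choices
        # should be (almost) all safe
        task = TaskSpec(0.0, 1.0, 30.0, 0.5)
        rec = run_bandit_task(Genome(0.5, 0.5, 0.5), task, 400, np.random.default_rng(9))
        assert np.mean(rec.choices[-100:] == SAFE) > 0.99

    def test_near_zero_negative_rate_yields_risk_seeking(self, risk_seeking_task):
        # Fixed genes in the low-alpha_n region keep choosing the risky
        # option in a risk-seeking task (the heatmap's risk-seeking region).
        n = 300
        rngs = spawn_agent_rngs(77, n)
        beh = simulate_population(
            np.full(n, 0.5), np.zeros(n), np.full(n, 0.25),
            risk_seeking_task, 500, rngs,
        )
        assert (1.0 - beh.risk_aversion.mean()) > 0.5

    def test_asymmetric_with_equal_rates_reproduces_single_rate_bitwise(
        self, risk_aversion_task
    ):
        asym = run_bandit_task(
            Genome(0.37, 0.37, 0.2), risk_aversion_task, 300, np.random.default_rng(5)
        )
        single = run_bandit_task(
            Genome.single_rate(0.37, 0.2), risk_aversion_task, 300,
            np.random.default_rng(5),
        )
        assert np.array_equal(asym.choices, single.choices)
        assert np.array_equal(asym.rewards, single.rewards)
        assert asym.final_V == single.final_V


class TestPopulationExecution:
    def test_batch_matches_per_agent_sequential_runs(
        self, risk_aversion_task, risk_seeking_task
    ):
        tasks = [risk_aversion_task, risk_seeking_task]
        n_agents, n_trials = 6, 60
        genes = np.random.default_rng(1)
        ap, an = genes.random(n_agents), genes.random(n_agents)
        beta = genes.random(n_agents) * 0.5
        ss = np.random.SeedSequence(99)
        beh = simulate_population(
            ap, an, beta, tasks, n_trials, spawn_agent_rngs(ss, n_agents), window=10
        )
        replay = spawn_agent_rngs(np.random.SeedSequence(99), n_agents)
        for i in range(n_agents):
            records = run_bandit_tasks(
                Genome(ap[i], an[i], beta[i]), tasks, n_trials, replay[i]
            )
            for k, rec in enumerate(records):
                assert beh.safe_counts[i, k] == np.sum(rec.choices == SAFE)
                assert beh.safe_counts_window[i, k] == np.sum(rec.choices[-10:] == SAFE)
            total = sum(rec.rewards.sum() for rec in records)
            assert beh.payoff_sum[i] == pytest.approx(total, rel=1e-12)

    def test_stream_count_must_match_population(self, risk_aversion_task):
        with pytest.raises(ValueError, match="stream"):
            simulate_population(
                np.ones(3), np.ones(3), np.ones(3) * 0.2,
                risk_aversion_task, 10, spawn_agent_rngs(0, 2),
            )
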