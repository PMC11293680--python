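"""Fitness, selection, mutation, and the generation loop."""

import numpy as np
import pytest
from scipy import stats

from evobandit import (
    Genome,
    Population,
    adjust_negative_fitness,
    compute_fitness,
    init_population,
    mutate_genome,
    mutate_population,
    niv_index,
    run_evolution,
    select_parents,
)


class TestComputeFitness:
    def test_constant_payoffs(self):
        fitness = compute_fitness(np.full((3, 10), 7.0))
        assert np.allclose(fitness, 27.0)

    def test_baseline_added_to_mean(self):
        payoffs = [np.full(2000, 10.0), np.linspace(0, 20, 2000)]
        fitness = compute_fitness(payoffs)
        assert fitness[0] == pytest.approx(30.0)
        assert fitness[1] == pytest.approx(30.0)

    def test_unequal_trial_counts_rejected(self):
        with pytest.raises(ValueError, match="same total trial count"):
            compute_fitness([np.ones(10), np.ones(9)])


class TestAdjustNegativeFitness:
    def test_shift_by_abs_min_plus_point_one(self):
        adjusted = adjust_negative_fitness(np.array([-5.0, 3.0]))
        assert np.allclose(adjusted, [0.1, 8.1])
        assert adjusted.min() == pytest.approx(0.1)

    def test_all_positive_unchanged(self):
        fitness = np.array([2.0, 5.0])
        assert np.array_equal(adjust_negative_fitness(fitness), fitness)

    def test_zero_is_not_negative(self):
        fitness = np.array([0.0, 2.0])
        assert np.array_equal(adjust_negative_fitness(fitness), fitness)


class TestSelectParents:
    def test_uniform_fitness_is_multinomially_uniform(self, rng):
        n = 10**4
        counts = np.bincount(select_parents(np.ones(n), rng), minlength=n)
        # chi-square goodness of fit against the uniform expectation
        assert stats.chisquare(counts).pvalue > 0.001

    def test_dominant_agent_receives_proportional_offspring(self, rng):
        n = 1000
        fitness = np.ones(n)
        fitness[0] = 99.0 * (n - 1)  # holds 99% of total fitness
        counts = np.bincount(select_parents(fitness, rng), minlength=n)
        sd = np.sqrt(n * 0.99 * 0.01)
        assert abs(counts[0] - 990) <= 3 * sd

    def test_single_agent_population(self, rng):
        assert np.array_equal(select_parents(np.array([5.0]), rng), [0])

    def test_non_positive_fitness_rejected(self, rng):
        with pytest.raises(ValueError, match="positive"):
            select_parents(np.array([1.0, 0.0]), rng)


class TestMutation:
    def test_zero_sd_is_identity(self, rng):
        g = Genome(0.3, 0.7, 0.25)
        assert mutate_genome(g, sd_alpha=0.0, sd_beta=0.0, rng=rng) == g

    def test_unbiased_far_from_bounds(self, rng):
        n = 10**5
        pop = Population(np.full(n, 0.5), np.full(n, 0.5), np.full(n, 0.25))
        out = mutate_population(pop, rng=rng)
        assert abs(out.alpha_p.mean() - 0.5) < 4 * 0.01 / np.sqrt(n)
        assert abs(out.beta.mean() - 0.25) < 4 * 0.005 / np.sqrt(n)
        assert out.alpha_p.min() >= 0 and out.alpha_p.max() <= 1

    def test_truncation_keeps_boundary_gene_in_range(self, rng):
        n = 10**5
        pop = Population(np.full(n, 0.5), np.zeros(n), np.full(n, 0.25))
        out = mutate_population(pop, rng=rng)
        assert out.alpha_n.min() >= 0.0
        assert out.alpha_n.max() <= 1.0
        # truncation, not clipping: no probability atom exactly at the bound
        assert np.sum(out.alpha_n == 0.0) == 0

    def test_single_rate_mutates_jointly(self, rng):
        pop = Population(np.full(10, 0.5), np.full(10, 0.5), np.full(10, 0.25),
                         variant="single_rate")
        out = mutate_population(pop, rng=rng)
        assert np.array_equal(out.alpha_p, out.alpha_n)


class TestInitPopulation:
    def test_uniform_moments(self, rng):
        n = 10**5
        pop = init_population(n, "asymmetric", rng)
        se = (1 / np.sqrt(12)) / np.sqrt(n)
        assert abs(pop.alpha_p.mean() - 0.5) < 4 * se
        assert abs(pop.alpha_n.mean() - 0.5) < 4 * se
        assert abs(pop.beta.mean() - 0.25) < 4 * se / 2
        assert pop.beta.max() <= 0.5

    def test_first_generation_niv_index_symmetric_about_zero(self, rng):
        pop = init_population(10**5, "asymmetric", rng)
        index = niv_index(pop.alpha_p, pop.alpha_n)
        n_pos = int(np.sum(index > 0))
        n = int(np.sum(index != 0))
        assert stats.binomtest(n_pos, n, 0.5).pvalue > 0.001

    def test_single_rate_population_shares_one_rate(self, rng):
        pop = init_population(100, "single_rate", rng)
        assert np.array_equal(pop.alpha_p, pop.alpha_n)


class TestRunEvolution:
    def test_one_generation_contract(self, risk_aversion_task):
        res = run_evolution(
            risk_aversion_task, n_agents=30, n_generations=1, n_trials=20, seed=0
        )
        assert len(res.trace) == 1
        assert res.trace["generation"].iloc[0] == 0
        # final population is the mutated offspring of generation 0, so its
        # genes differ from (but stay close to) the recorded generation
        assert res.final.n_agents == 30
        assert not np.array_equal(res.final.alpha_p, res.initial.alpha_p)

    def test_deterministic_and_size_conserving(self, risk_aversion_task):
        kwargs = dict(n_agents=40, n_generations=8, n_trials=30, seed=21)
        a = run_evolution(risk_aversion_task, **kwargs)
        b = run_evolution(risk_aversion_task, **kwargs)
        assert a.trace.equals(b.trace)
        assert np.array_equal(a.final.alpha_p, b.final.alpha_p)
        assert np.array_equal(a.final.beta, b.final.beta)
        assert a.final.n_agents == a.initial.n_agents == 40

    def test_trace_records_one_risk_aversion_column_per_task(
        self, risk_aversion_task, risk_seeking_task
    ):
        res = run_evolution(
            [risk_aversion_task, risk_seeking_task],
            n_agents=20, n_generations=2, n_trials=10, seed=4,
        )
        assert "mean_risk_aversion_task2" in res.trace.columns

    def test_neutral_selection_gene_means_random_walk(self):
        # with fitness forced constant, selection is neutral and the mean
        # alpha_p drifts only by mutation noise: within 4*(sd/sqrt(N))*sqrt(G)
        rng = np.random.default_rng(8)
        n, generations = 1000, 100
        pop = init_population(n, "asymmetric", rng)
        start = pop.alpha_p.mean()
        for _ in range(generations):
            parents = select_parents(np.ones(n), rng)
            pop = Population(
                pop.alpha_p[parents], pop.alpha_n[parents], pop.beta[parents]
            )
            pop = mutate_population(pop, rng=rng)
        drift_bound = 4 * (0.01 / np.sqrt(n)) * np.sqrt(generations)
        # selection resampling adds genetic drift on top of mutation noise;
        # allow both contributions (initial SD/sqrt(N) per generation scale)
        drift_bound += 4 * (pop.alpha_p.std() / np.sqrt(n)) * np.sqrt(generations)
        assert abs(pop.alpha_p.mean() - start) < drift_bound
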