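"""One generation's life cycle and the multi-generation loop.

Each generation, every agent plays the environment's task(s); fitness is the
arithmetic mean of all payoffs an agent collected plus a baseline of 20.  If
the population minimum is negative, the whole population is shifted so the
minimum becomes exactly 0.1.  Offspring are then drawn with probability
proportional to fitness (roulette wheel, with replacement, whole-generation
replacement, no elitism) and every gene of every offspring is perturbed by
truncated Gaussian noise that keeps it inside its bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .agents import Genome, simulate_population, spawn_agent_rngs
from .tasks import TaskSpec

__all__ = [
    "Population",
    "EvolutionResult",
    "GENE_BOUNDS",
    "MUTATION_SD_ALPHA",
    "MUTATION_SD_BETA",
    "BASELINE_FITNESS",
    "init_population",
    "compute_fitness",
    "adjust_negative_fitness",
    "select_parents",
    "mutate_genome",
    "mutate_population",
    "run_evolution",
]

#: Closed gene bounds: learning rates in [0, 1], inverse temperature in [0, 0.5].
GENE_BOUNDS = {"alpha_p": (0.0, 1.0), "alpha_n": (0.0, 1.0), "beta": (0.0, 0.5)}

#: Mutation noise SDs: N(0, 0.01) for the learning rates, N(0, 0.005) for beta.
MUTATION_SD_ALPHA = 0.01
MUTATION_SD_BETA = 0.005

#: Baseline added to each agent's mean payoff when computing fitness.
BASELINE_FITNESS = 20.0


@dataclass
class Population:
    """Fixed-size collection of genomes, plus per-agent fitness once evaluated.

    Genes are stored as parallel arrays.  In the ``single_rate`` variant
    ``alpha_p`` and ``alpha_n`` hold the same values (one gene, mutated
    jointly).
    """

    alpha_p: np.ndarray
    alpha_n: np.ndarray
    beta: np.ndarray
    variant: str = "asymmetric"
    fitness: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alpha_p = np.asarray(self.alpha_p, dtype=float)
        self.alpha_n = np.asarray(self.alpha_n, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if not (self.alpha_p.shape == self.alpha_n.shape == self.beta.shape):
            raise ValueError("gene arrays must have equal shape")
        if self.variant == "single_rate" and not np.array_equal(
            self.alpha_p, self.alpha_n
        ):
            raise ValueError("single_rate populations carry one learning rate")

    @property
    def n_agents(self) -> int:
        return self.alpha_p.size

    def genome(self, i: int) -> Genome:
        return Genome(
            float(self.alpha_p[i]),
            float(self.alpha_n[i]),
            float(self.beta[i]),
            variant=self.variant,
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "agent_id": np.arange(self.n_agents),
                "alpha_p": self.alpha_p,
                "alpha_n": self.alpha_n,
                "beta": self.beta,
            }
        )
        if self.fitness is not None:
            frame["fitness"] = self.fitness
        return frame


@dataclass
class EvolutionResult:
    """Outcome of one evolutionary simulation.

    ``trace`` holds one row per evaluated generation (gene means/SDs and the
    mean risk-aversion rate per task, recorded before selection, so row 0 is
    the unevolved first generation).  ``initial`` and ``final`` are the
    generation-0 population and the offspring produced by the last
    selection-mutation cycle.
    """

    trace: pd.DataFrame
    initial: Population
    final: Population
    tasks: tuple[TaskSpec, ...]


def init_population(
    n_agents: int, variant: str, rng: np.random.Generator
) -> Population:
    """Initial population with genes drawn i.i.d. from the stated uniforms:
    Uniform[0, 1] for the learning rates, Uniform[0, 0.5] for beta."""
    if n_agents < 1:
        raise ValueError("n_agents must be at least 1")
    if variant == "asymmetric":
        alpha_p = rng.random(n_agents)
        alpha_n = rng.random(n_agents)
    elif variant == "single_rate":
        alpha_p = rng.random(n_agents)
        alpha_n = alpha_p.copy()
    else:
        raise ValueError(f"unknown variant: {variant!r}")
    beta = rng.uniform(0.0, 0.5, n_agents)
    return Population(alpha_p, alpha_n, beta, variant=variant)


def compute_fitness(payoffs, baseline: float = BASELINE_FITNESS) -> np.ndarray:
    """Fitness = mean of all payoffs an agent received, plus the baseline.

    ``payoffs`` is an (N, n_trials) array or a sequence of equal-length
    per-agent payoff vectors (all tasks and trials concatenated).
    """
    rows = [np.asarray(p, dtype=float).ravel() for p in payoffs]
    if len({r.size for r in rows}) != 1:
        raise ValueError("every agent must have the same total trial count")
    return np.array([r.mean() for r in rows]) + baseline


def adjust_negative_fitness(fitness: np.ndarray) -> np.ndarray:
    """Shift fitness so its minimum is exactly 0.1 when any value is negative.

    If ``min(fitness) < 0`` the absolute value of the minimum plus 0.1 is
    added to every agent; otherwise fitness is returned unchanged (zero is
    not negative).
    """
    fitness = np.asarray(fitness, dtype=float)
    lowest = fitness.min()
    if lowest < 0:
        return fitness + abs(lowest) + 0.1
    return fitness


def select_parents(fitness: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Fitness-proportional parent indices, N draws with replacement."""
    fitness = np.asarray(fitness, dtype=float)
    if np.any(fitness <= 0):
        raise ValueError("selection requires strictly positive fitness")
    p = fitness / fitness.sum()
    return rng.choice(fitness.size, size=fitness.size, p=p)


def _truncated_perturb(values, sd, lower, upper, rng):
    # Rejection-resample the noise until the mutated gene is in range: a
    # truncated-normal draw, not a clip, so no probability atom at the bounds.
    values = np.asarray(values, dtype=float)
    if sd == 0:
        return values.copy()
    out = values + rng.normal(0.0, sd, size=values.shape)
    bad = (out < lower) | (out > upper)
    while bad.any():
        out[bad] = values[bad] + rng.normal(0.0, sd, size=int(bad.sum()))
        bad = (out < lower) | (out > upper)
    return out


def mutate_genome(
    genome: Genome,
    sd_alpha: float = MUTATION_SD_ALPHA,
    sd_beta: float = MUTATION_SD_BETA,
    rng: np.random.Generator | None = None,
) -> Genome:
    """Perturb each gene with independent truncated Gaussian noise.

    Learning rates receive noise of SD ``sd_alpha``, beta of SD ``sd_beta``;
    the result is guaranteed inside the gene bounds.  A single-rate genome's
    one learning rate receives one draw.
    """
    if rng is None:
        raise ValueError("an explicit random generator is required")
    if genome.variant == "single_rate":
        alpha = float(_truncated_perturb([genome.alpha], sd_alpha, 0.0, 1.0, rng)[0])
        beta = float(_truncated_perturb([genome.beta], sd_beta, 0.0, 0.5, rng)[0])
        return Genome.single_rate(alpha, beta)
    alpha_p = float(_truncated_perturb([genome.alpha_p], sd_alpha, 0.0, 1.0, rng)[0])
    alpha_n = float(_truncated_perturb([genome.alpha_n], sd_alpha, 0.0, 1.0, rng)[0])
    beta = float(_truncated_perturb([genome.beta], sd_beta, 0.0, 0.5, rng)[0])
    return Genome(alpha_p, alpha_n, beta)


def mutate_population(
    population: Population,
    sd_alpha: float = MUTATION_SD_ALPHA,
    sd_beta: float = MUTATION_SD_BETA,
    rng: np.random.Generator | None = None,
) -> Population:
    """Vectorized mutation of every genome in a population."""
    if rng is None:
        raise ValueError("an explicit random generator is required")
    if population.variant == "single_rate":
        alpha = _truncated_perturb(population.alpha_p, sd_alpha, 0.0, 1.0, rng)
        alpha_p, alpha_n = alpha, alpha.copy()
    else:
        alpha_p = _truncated_perturb(population.alpha_p, sd_alpha, 0.0, 1.0, rng)
        alpha_n = _truncated_perturb(population.alpha_n, sd_alpha, 0.0, 1.0, rng)
    beta = _truncated_perturb(population.beta, sd_beta, 0.0, 0.5, rng)
    return Population(alpha_p, alpha_n, beta, variant=population.variant)


def run_evolution(
    tasks: Sequence[TaskSpec] | TaskSpec,
    *,
    n_agents: int,
    n_generations: int,
    n_trials: int,
    variant: str = "asymmetric",
    seed: int | np.random.SeedSequence | None = None,
    baseline_fitness: float = BASELINE_FITNESS,
    sd_alpha: float = MUTATION_SD_ALPHA,
    sd_beta: float = MUTATION_SD_BETA,
) -> EvolutionResult:
    """Evolve a population on a fixed task or task battery.

    Each generation: evaluate all agents (independent values per task, genes
    shared across tasks), record the trace row, compute fitness, adjust
    negatives, select parents proportionally to fitness, and mutate the
    offspring.  Generation summaries are recorded before selection, so the
    first trace row describes the unevolved population.  The whole run is a
    deterministic function of the seed.
    """
    if isinstance(tasks, TaskSpec):
        tasks = (tasks,)
    tasks = tuple(tasks)
    if n_generations < 1:
        raise ValueError("n_generations must be at least 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    init_ss, agents_ss, evo_ss = ss.spawn(3)
    evo_rng = np.random.default_rng(evo_ss)
    population = init_population(n_agents, variant, np.random.default_rng(init_ss))
    initial = Population(
        population.alpha_p.copy(),
        population.alpha_n.copy(),
        population.beta.copy(),
        variant=variant,
    )
    agent_rngs = spawn_agent_rngs(agents_ss, n_agents)
    total_trials = n_trials * len(tasks)
    rows = []
    for generation in range(n_generations):
        behavior = simulate_population(
            population.alpha_p,
            population.alpha_n,
            population.beta,
            tasks,
            n_trials,
            agent_rngs,
        )
        fitness = behavior.payoff_sum / total_trials + baseline_fitness
        population.fitness = fitness
        row = {
            "generation": generation,
            "mean_alpha_p": population.alpha_p.mean(),
            "sd_alpha_p": population.alpha_p.std(),
            "mean_alpha_n": population.alpha_n.mean(),
            "sd_alpha_n": population.alpha_n.std(),
            "mean_beta": population.beta.mean(),
            "sd_beta": population.beta.std(),
        }
        task_rates = behavior.risk_aversion.mean(axis=0)
        for k in range(len(tasks)):
            row[f"mean_risk_aversion_task{k + 1}"] = task_rates[k]
        rows.append(row)
        adjusted = adjust_negative_fitness(fitness)
        parents = select_parents(adjusted, evo_rng)
        offspring = Population(
            population.alpha_p[parents].copy(),
            population.alpha_n[parents].copy(),
            population.beta[parents].copy(),
            variant=variant,
        )
        population = mutate_population(offspring, sd_alpha, sd_beta, evo_rng)
    return EvolutionResult(
        trace=pd.DataFrame(rows),
        initial=initial,
        final=population,
        tasks=tasks,
    )
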