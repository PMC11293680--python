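"""The learning mechanism: value updates, softmax choice, and bandit play.

Agents learn option values with a Rescorla-Wagner style delta rule.  The
asymmetric variant applies a positive learning rate ``alpha_p`` to positive
reward prediction errors (delta >= 0) and a negative learning rate
``alpha_n`` to negative ones; the single-rate variant uses one ``alpha`` for
both, which is exactly the asymmetric rule with ``alpha_p == alpha_n``.
Choices follow a softmax over the two option values with inverse temperature
``beta``.

Two execution paths are provided: :func:`run_bandit_task` steps one agent
through one task (the readable reference path), and
:func:`simulate_population` advances a whole population through a battery of
tasks via a compiled kernel.  Given the same per-agent random sub-streams
the two paths are bit-identical; each trial consumes one uniform draw (the
choice) followed by one standard-normal draw (the payoff), with each agent's
uniforms for a whole generation drawn before its normals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._kernels import EXP_CLIP, play_population
from .tasks import RISKY, SAFE, TaskSpec

__all__ = [
    "VARIANTS",
    "Genome",
    "BehaviorRecord",
    "PopulationBehavior",
    "choice_probability",
    "update_value_asymmetric",
    "update_value_single",
    "run_bandit_task",
    "run_bandit_tasks",
    "simulate_population",
    "spawn_agent_rngs",
]

VARIANTS = ("asymmetric", "single_rate")


@dataclass(frozen=True)
class Genome:
    """Heritable parameters of one agent.

    ``alpha_p`` and ``alpha_n`` live in [0, 1], ``beta`` in [0, 0.5].  In the
    ``single_rate`` variant the two learning rates are a single gene and must
    be equal; :meth:`single_rate` builds such a genome from one ``alpha``.
    """

    alpha_p: float
    alpha_n: float
    beta: float
    variant: str = "asymmetric"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant: {self.variant!r}")
        if not (0.0 <= self.alpha_p <= 1.0 and 0.0 <= self.alpha_n <= 1.0):
            raise ValueError("learning rates must lie in [0, 1]")
        if not 0.0 <= self.beta <= 0.5:
            raise ValueError("beta must lie in [0, 0.5]")
        if self.variant == "single_rate" and self.alpha_p != self.alpha_n:
            raise ValueError("single_rate genomes carry one learning rate")

    @classmethod
    def single_rate(cls, alpha: float, beta: float) -> "Genome":
        return cls(alpha, alpha, beta, variant="single_rate")

    @property
    def alpha(self) -> float:
        """The shared learning rate of a single-rate genome."""
        if self.variant != "single_rate":
            raise AttributeError("alpha is defined for single_rate genomes")
        return self.alpha_p


@dataclass
class BehaviorRecord:
    """One agent's history on one task: choices (0=risky, 1=safe), rewards,
    and the final option values ``(V_risky, V_safe)``."""

    choices: np.ndarray
    rewards: np.ndarray
    final_V: tuple[float, float]

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=np.int8)
        self.rewards = np.asarray(self.rewards, dtype=float)
        if self.choices.shape != self.rewards.shape:
            raise ValueError("choices and rewards must have equal length")

    @property
    def n_trials(self) -> int:
        return self.choices.size


@dataclass
class PopulationBehavior:
    """Aggregate play of N agents on K tasks.

    ``safe_counts`` and ``safe_counts_window`` have shape (N, K);
    ``payoff_sum`` has shape (N,) and totals each agent's rewards across all
    tasks and trials.
    """

    safe_counts: np.ndarray
    safe_counts_window: np.ndarray
    payoff_sum: np.ndarray
    n_trials: int
    window: int

    @property
    def risk_aversion(self) -> np.ndarray:
        """Per-agent, per-task fraction of safe choices over all trials."""
        return self.safe_counts / self.n_trials

    @property
    def risk_aversion_window(self) -> np.ndarray:
        """Safe-choice fraction over the last ``window`` trials of each task."""
        return self.safe_counts_window / self.window

    @property
    def mean_payoff(self) -> np.ndarray:
        """Per-agent mean payoff over every trial played."""
        return self.payoff_sum / (self.n_trials * self.safe_counts.shape[1])


def choice_probability(V: Sequence[float], beta: float) -> float:
    """Softmax probability of choosing the risky option (option 1).

    ``p = 1 / (1 + exp(-beta * (V_risky - V_safe)))``.  The exponent is
    clipped at +/-700 so extreme value differences saturate at 0/1 instead of
    overflowing.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    x = beta * (float(V[RISKY]) - float(V[SAFE]))
    if x > EXP_CLIP:
        return 1.0
    if x < -EXP_CLIP:
        return 0.0
    return 1.0 / (1.0 + math.exp(-x))


def update_value_asymmetric(
    V: Sequence[float],
    chosen: int,
    reward: float,
    alpha_p: float,
    alpha_n: float,
) -> np.ndarray:
    """Asymmetric delta-rule update of the chosen option's value.

    ``delta = reward - V[chosen]`` is weighted by ``alpha_p`` when
    ``delta >= 0`` (the boundary case takes the positive branch) and by
    ``alpha_n`` when ``delta < 0``.  The unchosen option is not updated.
    Returns a new value array.
    """
    if not (0.0 <= alpha_p <= 1.0 and 0.0 <= alpha_n <= 1.0):
        raise ValueError("learning rates must lie in [0, 1]")
    V = np.array(V, dtype=float)
    delta = reward - V[chosen]
    rate = alpha_p if delta >= 0.0 else alpha_n
    V[chosen] += rate * delta
    return V


def update_value_single(
    V: Sequence[float], chosen: int, reward: float, alpha: float
) -> np.ndarray:
    """Single-rate delta-rule update; identical to the asymmetric rule with
    ``alpha_p == alpha_n == alpha``."""
    return update_value_asymmetric(V, chosen, reward, alpha, alpha)


def run_bandit_task(
    genome: Genome,
    task: TaskSpec,
    n_trials: int,
    rng: np.random.Generator,
) -> BehaviorRecord:
    """Step one agent through ``n_trials`` trials of one task.

    Values start at zero.  All choice uniforms are drawn first, then all
    payoff normals, matching the draw layout of the population kernel so the
    same sub-stream yields the same behavior on either path.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    u = rng.random(n_trials)
    z = rng.standard_normal(n_trials)
    return _play_one(genome, task, u, z)


def run_bandit_tasks(
    genome: Genome,
    tasks: Sequence[TaskSpec],
    n_trials: int,
    rng: np.random.Generator,
) -> list[BehaviorRecord]:
    """One agent through several tasks with independent values per task.

    The agent's uniforms for the whole battery are drawn before its normals
    (one generation's worth of randomness), as in the population kernel.
    """
    total = n_trials * len(tasks)
    u = rng.random(total)
    z = rng.standard_normal(total)
    records = []
    for k, task in enumerate(tasks):
        sl = slice(k * n_trials, (k + 1) * n_trials)
        records.append(_play_one(genome, task, u[sl], z[sl]))
    return records


def _play_one(genome, task, u, z):
    V = np.zeros(2)
    n = u.size
    choices = np.empty(n, dtype=np.int8)
    rewards = np.empty(n)
    for t in range(n):
        p_risky = choice_probability(V, genome.beta)
        c = RISKY if u[t] < p_risky else SAFE
        reward = task.means[c] + task.sigmas[c] * z[t]
        V = update_value_asymmetric(V, c, reward, genome.alpha_p, genome.alpha_n)
        choices[t] = c
        rewards[t] = reward
    return BehaviorRecord(choices=choices, rewards=rewards, final_V=(V[0], V[1]))


def spawn_agent_rngs(
    seed: int | np.random.SeedSequence, n_agents: int
) -> list[np.random.Generator]:
    """Independent per-agent random sub-streams from one seed.

    Streams persist across generations: each generation of play consumes the
    next block of draws from each agent slot's stream.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n_agents)]


def simulate_population(
    alpha_p: np.ndarray,
    alpha_n: np.ndarray,
    beta: np.ndarray,
    tasks: Sequence[TaskSpec] | TaskSpec,
    n_trials: int,
    agent_rngs: Sequence[np.random.Generator],
    window: int = 100,
) -> PopulationBehavior:
    """Advance a whole population through a battery of tasks.

    Each agent plays every task independently (fresh zero values per task)
    with its own random sub-stream; results are bit-identical to running
    :func:`run_bandit_tasks` per agent on the same streams.  ``window`` (the
    number of final trials tallied separately, for late-trial risk-aversion
    rates) is clamped to ``n_trials``.
    """
    if isinstance(tasks, TaskSpec):
        tasks = [tasks]
    alpha_p = np.ascontiguousarray(alpha_p, dtype=float)
    alpha_n = np.ascontiguousarray(alpha_n, dtype=float)
    beta = np.ascontiguousarray(beta, dtype=float)
    n_agents = alpha_p.size
    if len(agent_rngs) != n_agents:
        raise ValueError("need exactly one random stream per agent")
    window = min(window, n_trials)
    mu = np.array([t.means for t in tasks])
    sigma = np.array([t.sigmas for t in tasks])
    total = n_trials * len(tasks)
    uniforms = np.empty((n_agents, total))
    z = np.empty((n_agents, total))
    for i, r in enumerate(agent_rngs):
        uniforms[i] = r.random(total)
        z[i] = r.standard_normal(total)
    safe_counts, safe_window, payoff_sum = play_population(
        alpha_p, alpha_n, beta, mu, sigma, uniforms, z, n_trials, window
    )
    return PopulationBehavior(
        safe_counts=safe_counts,
        safe_counts_window=safe_window,
        payoff_sum=payoff_sum,
        n_trials=n_trials,
        window=window,
    )
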