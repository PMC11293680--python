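"""The study designs, as runnable pipelines.

Four experiments are provided:

* **single-task** — replicate evolutionary runs of one population on one
  bandit task;
* **multiple-task** — populations evolve while playing a randomly drawn,
  fixed set of four tasks per simulation, with the number of risk-seeking
  tasks (0-4) as the condition;
* **risk-tendency assay** — evolved populations are phenotyped on four
  equal-expected-value tasks (two gain-domain, two loss-domain), scoring
  each agent's late-trial risk aversion and its gain-minus-loss difference;
* **parameter heatmap** — behavior of fixed (alpha_p, alpha_n) combinations
  on one task with beta held constant, mapping which learning-rate regions
  produce risk-averse or risk-seeking learning.

Every experiment is a deterministic function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .agents import simulate_population, spawn_agent_rngs
from .evolution import EvolutionResult, Population, init_population, run_evolution
from .metrics import pearson_correlation
from .tasks import (
    TaskSet,
    TaskSpec,
    assay_domain,
    classify_task,
    equal_ev_assay_tasks,
    generate_single_task_grid,
    generate_task_set,
    negative_area_rate,
)

__all__ = [
    "SingleTaskResult",
    "MultiTaskSimulation",
    "MultiTaskResult",
    "HeatmapResult",
    "run_single_task_experiment",
    "run_multiple_task_experiment",
    "run_risk_tendency_assay",
    "run_parameter_heatmap",
    "run_first_generation_baseline",
    "probe_population",
]


@dataclass
class SingleTaskResult:
    """Replicate runs on one task plus their across-replicate summary."""

    task: TaskSpec
    runs: list[EvolutionResult]
    summary: pd.DataFrame


@dataclass
class MultiTaskSimulation:
    """One multiple-task simulation: its fixed four-task environment, the
    environment's negative-area rate, and the evolutionary result.  For the
    all-one-class conditions (0 or 4 risk-seeking tasks), ``probe_task`` and
    the probe rates record how the first and last generations behave on a
    randomly drawn task of the class they never evolved in."""

    task_set: TaskSet
    negative_area_rate: float
    result: EvolutionResult
    probe_task: TaskSpec | None = None
    probe_first: float | None = None
    probe_last: float | None = None


@dataclass
class MultiTaskResult:
    """All simulations of one condition plus the per-simulation summary.

    ``correlation`` is the Pearson r, across simulations, between the task
    set's negative-area rate and the final-generation mean positive learning
    rate (NaN when fewer than three simulations were run).
    """

    n_risk_seeking: int
    simulations: list[MultiTaskSimulation]
    summary: pd.DataFrame
    correlation: float


@dataclass
class HeatmapResult:
    """Mean risk aversion over a (alpha_p, alpha_n) grid at fixed beta.

    ``rates[i, j]`` is the mean safe-choice fraction for
    ``alpha_n = alpha_values[i]``, ``alpha_p = alpha_values[j]``.
    """

    task: TaskSpec
    beta: float
    alpha_values: np.ndarray
    rates: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        i_n, i_p = np.meshgrid(
            np.arange(self.alpha_values.size),
            np.arange(self.alpha_values.size),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "alpha_n": self.alpha_values[i_n.ravel()],
                "alpha_p": self.alpha_values[i_p.ravel()],
                "risk_aversion": self.rates.ravel(),
            }
        )


def _first_last_rates(trace: pd.DataFrame, task_indices: Sequence[int]):
    cols = [f"mean_risk_aversion_task{k + 1}" for k in task_indices]
    if not cols:
        return np.nan, np.nan
    return (
        float(trace.iloc[0][cols].mean()),
        float(trace.iloc[-1][cols].mean()),
    )


def run_single_task_experiment(
    task: TaskSpec,
    *,
    n_replicates: int = 10,
    n_agents: int = 10_000,
    n_generations: int = 5_000,
    n_trials: int = 500,
    variant: str = "asymmetric",
    seed: int | np.random.SeedSequence | None = None,
) -> SingleTaskResult:
    """Independent evolutionary replicates of one population on one task.

    The summary row aggregates, across replicates, the final-generation gene
    means (mean and SD of the per-replicate means) and the first- and
    last-generation mean risk-aversion rates.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    runs = [
        run_evolution(
            task,
            n_agents=n_agents,
            n_generations=n_generations,
            n_trials=n_trials,
            variant=variant,
            seed=child,
        )
        for child in ss.spawn(n_replicates)
    ]
    final_ap = np.array([r.final.alpha_p.mean() for r in runs])
    final_an = np.array([r.final.alpha_n.mean() for r in runs])
    final_beta = np.array([r.final.beta.mean() for r in runs])
    first = np.array([r.trace["mean_risk_aversion_task1"].iloc[0] for r in runs])
    last = np.array([r.trace["mean_risk_aversion_task1"].iloc[-1] for r in runs])
    summary = pd.DataFrame(
        [
            {
                "label": task.label,
                "class": classify_task(task),
                "n_replicates": n_replicates,
                "mean_final_alpha_p": final_ap.mean(),
                "sd_final_alpha_p": final_ap.std(),
                "mean_final_alpha_n": final_an.mean(),
                "sd_final_alpha_n": final_an.std(),
                "mean_final_beta": final_beta.mean(),
                "sd_final_beta": final_beta.std(),
                "first_gen_risk_aversion": first.mean(),
                "last_gen_risk_aversion": last.mean(),
            }
        ]
    )
    return SingleTaskResult(task=task, runs=runs, summary=summary)


def probe_population(
    population: Population,
    task: TaskSpec,
    n_trials: int,
    seed: int | np.random.SeedSequence,
) -> float:
    """Mean risk-aversion rate of an existing population on one task."""
    rngs = spawn_agent_rngs(seed, population.n_agents)
    behavior = simulate_population(
        population.alpha_p, population.alpha_n, population.beta, task, n_trials, rngs
    )
    return float(behavior.risk_aversion.mean())


def run_multiple_task_experiment(
    n_risk_seeking: int,
    *,
    n_simulations: int = 100,
    n_agents: int = 1_000,
    n_generations: int = 5_000,
    n_trials: int = 500,
    grid: Sequence[TaskSpec] | None = None,
    variant: str = "asymmetric",
    seed: int | np.random.SeedSequence | None = None,
) -> MultiTaskResult:
    """Replicate multiple-task simulations for one condition.

    Each simulation draws its own four-task environment (exactly
    ``n_risk_seeking`` risk-seeking tasks, sampled without replacement from
    the grid — by default the ``|D| = 20`` grid), evolves a population on
    it, and records the environment's negative-area rate.  Option values are
    task-independent within an agent; genes are shared across tasks, and
    fitness averages the payoffs of all four tasks.

    For the pure conditions (0 or 4), each simulation additionally probes
    the first and last generations on a randomly drawn task of the class
    absent from its environment.
    """
    if not 0 <= n_risk_seeking <= 4:
        raise ValueError("n_risk_seeking must be between 0 and 4")
    if grid is None:
        grid = generate_single_task_grid(20.0)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    simulations: list[MultiTaskSimulation] = []
    rows = []
    for sim_index, sim_ss in enumerate(ss.spawn(n_simulations)):
        taskset_ss, evo_ss, probe_ss = sim_ss.spawn(3)
        task_set = generate_task_set(
            n_risk_seeking, grid, np.random.default_rng(taskset_ss)
        )
        result = run_evolution(
            task_set.tasks,
            n_agents=n_agents,
            n_generations=n_generations,
            n_trials=n_trials,
            variant=variant,
            seed=evo_ss,
        )
        nar = negative_area_rate(task_set)
        classes = [classify_task(t) for t in task_set.tasks]
        rs_idx = [k for k, c in enumerate(classes) if c == "risk_seeking"]
        ra_idx = [k for k, c in enumerate(classes) if c == "risk_aversion"]
        first_rs, last_rs = _first_last_rates(result.trace, rs_idx)
        first_ra, last_ra = _first_last_rates(result.trace, ra_idx)
        sim = MultiTaskSimulation(
            task_set=task_set, negative_area_rate=nar, result=result
        )
        if n_risk_seeking in (0, 4):
            missing = "risk_seeking" if n_risk_seeking == 0 else "risk_aversion"
            pool = [t for t in grid if classify_task(t) == missing]
            pick_ss, first_ss, last_ss = probe_ss.spawn(3)
            probe_task = pool[
                int(np.random.default_rng(pick_ss).integers(len(pool)))
            ]
            sim.probe_task = probe_task
            sim.probe_first = probe_population(
                result.initial, probe_task, n_trials, first_ss
            )
            sim.probe_last = probe_population(
                result.final, probe_task, n_trials, last_ss
            )
            if missing == "risk_seeking":
                first_rs, last_rs = sim.probe_first, sim.probe_last
            else:
                first_ra, last_ra = sim.probe_first, sim.probe_last
        simulations.append(sim)
        rows.append(
            {
                "simulation": sim_index,
                "negative_area_rate": nar,
                "final_mean_alpha_p": result.final.alpha_p.mean(),
                "final_mean_alpha_n": result.final.alpha_n.mean(),
                "final_mean_beta": result.final.beta.mean(),
                "first_gen_risk_aversion_rs": first_rs,
                "last_gen_risk_aversion_rs": last_rs,
                "first_gen_risk_aversion_ra": first_ra,
                "last_gen_risk_aversion_ra": last_ra,
            }
        )
    summary = pd.DataFrame(rows)
    if n_simulations >= 3 and summary["negative_area_rate"].std() > 0:
        correlation = pearson_correlation(
            summary["negative_area_rate"], summary["final_mean_alpha_p"]
        )
    else:
        correlation = float("nan")
    return MultiTaskResult(
        n_risk_seeking=n_risk_seeking,
        simulations=simulations,
        summary=summary,
        correlation=correlation,
    )


def run_risk_tendency_assay(
    populations: Sequence[Population],
    *,
    n_trials: int = 500,
    window: int = 100,
    seed: int | np.random.SeedSequence | None = None,
) -> pd.DataFrame:
    """Phenotype pooled populations on the four equal-EV assay tasks.

    Every agent plays all four tasks with fresh zero values.  Per agent, the
    table records the late-trial (last ``window`` of ``n_trials``)
    risk-aversion rate in each task, the gain- and loss-domain means, and
    their difference (positive = more risk averse in the gain domain, the
    prospect-theory pattern).
    """
    if not populations:
        raise ValueError("at least one population is required")
    tasks = equal_ev_assay_tasks()
    domains = [assay_domain(t) for t in tasks]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    frames = []
    for pop_index, (population, pop_ss) in enumerate(
        zip(populations, ss.spawn(len(populations)))
    ):
        rngs = spawn_agent_rngs(pop_ss, population.n_agents)
        behavior = simulate_population(
            population.alpha_p,
            population.alpha_n,
            population.beta,
            tasks,
            n_trials,
            rngs,
            window=window,
        )
        rates = behavior.risk_aversion_window
        frame = population.to_frame().drop(columns=["fitness"], errors="ignore")
        frame.insert(0, "population", pop_index)
        for k in range(len(tasks)):
            frame[f"rate_task{k + 1}"] = rates[:, k]
        gain_cols = [f"rate_task{k + 1}" for k, d in enumerate(domains) if d == "gain"]
        loss_cols = [f"rate_task{k + 1}" for k, d in enumerate(domains) if d == "loss"]
        frame["gain_mean"] = frame[gain_cols].mean(axis=1)
        frame["loss_mean"] = frame[loss_cols].mean(axis=1)
        frame["difference"] = frame["gain_mean"] - frame["loss_mean"]
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def run_parameter_heatmap(
    task: TaskSpec,
    *,
    beta: float = 0.25,
    step: float = 0.01,
    n_trials: int = 500,
    repeats: int = 1,
    seed: int | np.random.SeedSequence | None = None,
) -> HeatmapResult:
    """Risk aversion of fixed learning-rate combinations on one task.

    Both learning rates range over ``0, step, ..., 1`` (the step must divide
    1 evenly) with beta held fixed.  Each cell's rate is the mean safe-choice
    fraction over ``n_trials`` trials, averaged over ``repeats`` independent
    runs (one run by default).

    Sub-stream layout (reproducible per cell): the seed is spawned into one
    child per repeat; each repeat child is spawned into one stream per cell
    in row-major order, rows indexed by alpha_n and columns by alpha_p.
    """
    n_steps = round(1.0 / step)
    if abs(n_steps * step - 1.0) > 1e-9:
        raise ValueError(f"step must divide 1 evenly, got {step}")
    alpha_values = np.linspace(0.0, 1.0, n_steps + 1)
    n_cells = alpha_values.size ** 2
    grid_n, grid_p = np.meshgrid(alpha_values, alpha_values, indexing="ij")
    alpha_n = np.ascontiguousarray(grid_n.ravel())
    alpha_p = np.ascontiguousarray(grid_p.ravel())
    betas = np.full(n_cells, beta)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rates = np.zeros(n_cells)
    for repeat_ss in ss.spawn(repeats):
        rngs = spawn_agent_rngs(repeat_ss, n_cells)
        behavior = simulate_population(
            alpha_p, alpha_n, betas, task, n_trials, rngs
        )
        rates += behavior.risk_aversion[:, 0]
    rates /= repeats
    return HeatmapResult(
        task=task,
        beta=beta,
        alpha_values=alpha_values,
        rates=rates.reshape(alpha_values.size, alpha_values.size),
    )


def run_first_generation_baseline(
    *,
    n_agents: int = 1_000,
    n_sets_per_condition: int = 5,
    conditions: Sequence[int] = (1, 2, 3, 4),
    n_trials: int = 500,
    grid: Sequence[TaskSpec] | None = None,
    variant: str = "asymmetric",
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[float, pd.DataFrame]:
    """Risk aversion of an unevolved population in risk-seeking tasks.

    One population with uniform-random genes plays the risk-seeking tasks of
    randomly drawn four-task sets (no evolution).  Returns the grand mean
    safe-choice fraction over agents and risk-seeking tasks, plus a per-set
    detail table.  This is the first-generation behavioral baseline of the
    multiple-task protocol.
    """
    if grid is None:
        grid = generate_single_task_grid(20.0)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    init_ss, sets_ss = ss.spawn(2)
    population = init_population(n_agents, variant, np.random.default_rng(init_ss))
    rows = []
    task_means = []
    set_children = iter(sets_ss.spawn(len(conditions) * n_sets_per_condition))
    for condition in conditions:
        for set_index in range(n_sets_per_condition):
            child = next(set_children)
            draw_ss, play_ss = child.spawn(2)
            task_set = generate_task_set(
                condition, grid, np.random.default_rng(draw_ss)
            )
            rs_tasks = [
                t for t in task_set.tasks if classify_task(t) == "risk_seeking"
            ]
            rngs = spawn_agent_rngs(play_ss, n_agents)
            behavior = simulate_population(
                population.alpha_p,
                population.alpha_n,
                population.beta,
                rs_tasks,
                n_trials,
                rngs,
            )
            per_task = behavior.risk_aversion.mean(axis=0)
            task_means.extend(per_task.tolist())
            rows.append(
                {
                    "condition": condition,
                    "set_index": set_index,
                    "n_risk_seeking": len(rs_tasks),
                    "mean_risk_aversion": float(per_task.mean()),
                }
            )
    return float(np.mean(task_means)), pd.DataFrame(rows)
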