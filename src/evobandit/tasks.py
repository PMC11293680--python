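"""Two-armed Gaussian bandit environments.

Every experiment in this package runs on tasks of the same shape: two options
whose payoffs are drawn from fixed normal distributions, with option 1 (the
*risky* option) always having the larger standard deviation than option 2
(the *safe* option).  The sign of ``D = mu_risky - mu_safe`` determines
whether risk seeking or risk aversion is the rewarding strategy.

This module is the synthetic-data stage of the pipeline: it generates the
single-task grids, the random four-task sets used in the multiple-task
protocol, and the equal-expected-value assay tasks used to phenotype evolved
risk preferences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RISKY",
    "SAFE",
    "TaskSpec",
    "TaskSet",
    "classify_task",
    "sample_payoff",
    "generate_single_task_grid",
    "generate_full_grid",
    "generate_task_set",
    "negative_area_rate",
    "equal_ev_assay_tasks",
    "assay_domain",
    "tasks_to_frame",
    "tasks_from_frame",
    "parse_task_label",
]

#: Integer codes for the two options, used throughout the package.
RISKY, SAFE = 0, 1

#: Default layout of the single-task grid: safe-option means and risky-option
#: standard deviations crossed for each sign of D (35 tasks per sign).
DEFAULT_SAFE_MEANS = (-30.0, -20.0, -10.0, 0.0, 10.0, 20.0, 30.0)
DEFAULT_RISKY_SIGMAS = (10.0, 15.0, 20.0, 25.0, 30.0)
DEFAULT_SIGMA_SAFE = 5.0


@dataclass(frozen=True)
class TaskSpec:
    """One two-armed bandit environment.

    Parameters
    ----------
    mu_risky, sigma_risky
        Mean and standard deviation of the risky option's payoff distribution.
    mu_safe, sigma_safe
        Mean and standard deviation of the safe option's payoff distribution.
    label
        Optional human-readable name; auto-generated as
        ``"N(mu1,sd1) vs N(mu2,sd2)"`` when omitted.

    The risky option must be strictly riskier: ``sigma_risky > sigma_safe``,
    and both standard deviations must be positive.
    """

    mu_risky: float
    sigma_risky: float
    mu_safe: float
    sigma_safe: float
    label: str | None = None

    def __post_init__(self) -> None:
        if not (self.sigma_safe > 0 and self.sigma_risky > 0):
            raise ValueError("payoff standard deviations must be positive")
        if not self.sigma_risky > self.sigma_safe:
            raise ValueError(
                "sigma_risky must exceed sigma_safe "
                f"(got {self.sigma_risky} <= {self.sigma_safe})"
            )
        if self.label is None:
            object.__setattr__(self, "label", self.default_label())

    def default_label(self) -> str:
        def fmt(x: float) -> str:
            return f"{x:g}"

        return (
            f"N({fmt(self.mu_risky)},{fmt(self.sigma_risky)}) vs "
            f"N({fmt(self.mu_safe)},{fmt(self.sigma_safe)})"
        )

    @property
    def D(self) -> float:
        """Mean difference ``mu_risky - mu_safe``; its sign names the task."""
        return self.mu_risky - self.mu_safe

    @property
    def means(self) -> np.ndarray:
        """Option means in option order ``[risky, safe]``."""
        return np.array([self.mu_risky, self.mu_safe])

    @property
    def sigmas(self) -> np.ndarray:
        """Option standard deviations in option order ``[risky, safe]``."""
        return np.array([self.sigma_risky, self.sigma_safe])


@dataclass(frozen=True)
class TaskSet:
    """A fixed environment of four bandit tasks for one multiple-task run."""

    tasks: tuple[TaskSpec, TaskSpec, TaskSpec, TaskSpec]
    n_risk_seeking: int

    def __post_init__(self) -> None:
        if len(self.tasks) != 4:
            raise ValueError("a TaskSet holds exactly four tasks")
        n_rs = sum(1 for t in self.tasks if t.D > 0)
        if n_rs != self.n_risk_seeking:
            raise ValueError(
                f"task set contains {n_rs} risk-seeking tasks, "
                f"declared {self.n_risk_seeking}"
            )


def classify_task(task: TaskSpec) -> str:
    """Classify a task by the sign of ``D = mu_risky - mu_safe``.

    Returns ``"risk_seeking"`` when the risky option pays more on average
    (D > 0), ``"risk_aversion"`` when the safe option pays more (D < 0), and
    ``"equal_ev"`` when the expected values coincide.
    """
    if task.D > 0:
        return "risk_seeking"
    if task.D < 0:
        return "risk_aversion"
    return "equal_ev"


def sample_payoff(
    task: TaskSpec,
    option: int,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw payoff(s) from one option's normal distribution.

    ``option`` is :data:`RISKY` (0) or :data:`SAFE` (1).  With ``size=None``
    a scalar is returned.
    """
    if option not in (RISKY, SAFE):
        raise ValueError(f"option must be RISKY (0) or SAFE (1), got {option}")
    mu = task.means[option]
    sigma = task.sigmas[option]
    return rng.normal(mu, sigma, size=size)


def generate_single_task_grid(
    d_magnitude: float = 20.0,
    safe_means: Sequence[float] = DEFAULT_SAFE_MEANS,
    risky_sigmas: Sequence[float] = DEFAULT_RISKY_SIGMAS,
    sigma_safe: float = DEFAULT_SIGMA_SAFE,
) -> list[TaskSpec]:
    """Build the grid of single tasks for both signs of D.

    For every safe-option mean and risky-option SD, one risk-seeking task
    (``D = +|D|``) and one risk-aversion task (``D = -|D|``) are produced.
    The default layout crosses seven distribution locations with five risky
    SDs, giving 35 tasks per sign (70 per ``|D|``).
    """
    if d_magnitude <= 0:
        raise ValueError("d_magnitude must be positive")
    for s in risky_sigmas:
        if not s > sigma_safe:
            raise ValueError(
                f"every risky sigma must exceed sigma_safe={sigma_safe}, got {s}"
            )
    grid = []
    for sign in (+1.0, -1.0):
        for mu_safe in safe_means:
            for sigma_risky in risky_sigmas:
                grid.append(
                    TaskSpec(
                        mu_risky=mu_safe + sign * d_magnitude,
                        sigma_risky=float(sigma_risky),
                        mu_safe=float(mu_safe),
                        sigma_safe=float(sigma_safe),
                    )
                )
    return grid


def generate_full_grid(d_magnitudes: Sequence[float] = (20.0, 10.0)) -> list[TaskSpec]:
    """All single-task environments: the default grids for each ``|D|``."""
    grid: list[TaskSpec] = []
    for d in d_magnitudes:
        grid.extend(generate_single_task_grid(d))
    return grid


def generate_task_set(
    n_risk_seeking: int,
    grid: Sequence[TaskSpec],
    rng: np.random.Generator,
) -> TaskSet:
    """Sample a four-task environment with a fixed risk-seeking count.

    Exactly ``n_risk_seeking`` tasks are drawn uniformly without replacement
    from the grid's risk-seeking tasks and the remainder from its
    risk-aversion tasks.  The resulting set is held constant for a whole
    evolutionary simulation.
    """
    if not 0 <= n_risk_seeking <= 4:
        raise ValueError("n_risk_seeking must be between 0 and 4")
    rs = [t for t in grid if classify_task(t) == "risk_seeking"]
    ra = [t for t in grid if classify_task(t) == "risk_aversion"]
    n_ra = 4 - n_risk_seeking
    if len(rs) < n_risk_seeking or len(ra) < n_ra:
        raise ValueError(
            "grid too small: need at least "
            f"{n_risk_seeking} risk-seeking and {n_ra} risk-aversion tasks"
        )
    chosen: list[TaskSpec] = []
    if n_risk_seeking:
        idx = rng.choice(len(rs), size=n_risk_seeking, replace=False)
        chosen.extend(rs[i] for i in idx)
    if n_ra:
        idx = rng.choice(len(ra), size=n_ra, replace=False)
        chosen.extend(ra[i] for i in idx)
    return TaskSet(tasks=tuple(chosen), n_risk_seeking=n_risk_seeking)


def negative_area_rate(task_set: TaskSet) -> float:
    """Average probability mass below zero across a task set's options.

    For each of the eight option distributions the standard normal CDF mass
    below zero, ``Phi(-mu / sigma)``, is computed; the mean over all eight
    options is returned.  The rate summarises how loss-like the environment
    is: the more negatively located the payoff distributions, the higher it
    gets (it is monotonically non-increasing in every option mean).
    """
    mus = np.array([[t.mu_risky, t.mu_safe] for t in task_set.tasks])
    sigmas = np.array([[t.sigma_risky, t.sigma_safe] for t in task_set.tasks])
    return float(np.mean(stats.norm.cdf(-mus / sigmas)))


def equal_ev_assay_tasks() -> list[TaskSpec]:
    """The four equal-expected-value tasks used to assay risk tendency.

    Two gain-domain tasks (both option means positive) and two loss-domain
    tasks (both negative); in every task the risky option has SD 20 and the
    safe option SD 5, with identical means (D = 0).  Order: gain tasks first.
    """
    return [
        TaskSpec(20.0, 20.0, 20.0, 5.0, label="gain: N(20,20) vs N(20,5)"),
        TaskSpec(10.0, 20.0, 10.0, 5.0, label="gain: N(10,20) vs N(10,5)"),
        TaskSpec(-10.0, 20.0, -10.0, 5.0, label="loss: N(-10,20) vs N(-10,5)"),
        TaskSpec(-20.0, 20.0, -20.0, 5.0, label="loss: N(-20,20) vs N(-20,5)"),
    ]


def assay_domain(task: TaskSpec) -> str:
    """Domain of an equal-EV assay task: ``"gain"`` (mu > 0) or ``"loss"``."""
    if classify_task(task) != "equal_ev":
        raise ValueError("assay domain is defined for equal-EV tasks only")
    return "gain" if task.mu_risky > 0 else "loss"


def tasks_to_frame(tasks: Iterable[TaskSpec]) -> pd.DataFrame:
    """Tabulate tasks with their mean difference D and class label."""
    rows = [
        {
            "label": t.label,
            "mu_risky": t.mu_risky,
            "sigma_risky": t.sigma_risky,
            "mu_safe": t.mu_safe,
            "sigma_safe": t.sigma_safe,
            "D": t.D,
            "class": classify_task(t),
        }
        for t in tasks
    ]
    return pd.DataFrame(rows)


def tasks_from_frame(frame: pd.DataFrame) -> list[TaskSpec]:
    """Rebuild :class:`TaskSpec` objects from a :func:`tasks_to_frame` table."""
    return [
        TaskSpec(
            mu_risky=float(r.mu_risky),
            sigma_risky=float(r.sigma_risky),
            mu_safe=float(r.mu_safe),
            sigma_safe=float(r.sigma_safe),
            label=str(r.label),
        )
        for r in frame.itertuples()
    ]


_TASK_RE = re.compile(
    r"N\(\s*(-?\d+(?:\.\d+)?)\s*,\s*(-?\d+(?:\.\d+)?)\s*\)"
)


def parse_task_label(label: str) -> TaskSpec:
    """Parse a task from a label such as ``"N(30,10) vs N(10,5)"``.

    The first distribution is the risky option, the second the safe option,
    following the package-wide option ordering.
    """
    found = _TASK_RE.findall(label)
    if len(found) != 2:
        raise ValueError(f"cannot parse task label: {label!r}")
    (m1, s1), (m2, s2) = found
    return TaskSpec(float(m1), float(s1), float(m2), float(s2))
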