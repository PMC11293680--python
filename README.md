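# evobandit

Agent-based evolutionary simulations of **asymmetric reinforcement
learning** in risky two-armed bandit environments, for researchers in
behavioral ecology and computational cognition who study how innate learning
biases — rather than behaviors themselves — are shaped by natural selection.

## The model

Each agent learns the value of two options by a delta rule with separate
learning rates for positive and negative reward prediction errors:

```
V_{t+1}(a) = V_t(a) + alpha_p * delta_t   if delta_t >= 0
V_{t+1}(a) = V_t(a) + alpha_n * delta_t   if delta_t <  0

delta_t = R_t - V_t(a)
```

with values starting at zero and the unchosen option never updated.  Choices
follow a softmax with inverse temperature `beta`:

```
p(choose risky) = 1 / (1 + exp(-beta * (V(risky) - V(safe))))
```

Payoffs are drawn from fixed normal distributions; the *risky* option always
has the larger SD.  When the risky option also has the higher mean
(`D = mu_risky - mu_safe > 0`) the environment is a *risk-seeking task*;
when `D < 0` it is a *risk-aversion task*.

The three parameters `alpha_p, alpha_n in [0, 1]` and `beta in [0, 0.5]` are
genes.  Populations of asexual agents play the task(s) for a generation;
fitness is each agent's mean payoff plus a baseline of 20 (shifted so the
minimum is 0.1 if any fitness is negative); offspring are drawn with
probability proportional to fitness and mutated by truncated Gaussian noise
(SD 0.01 for the learning rates, 0.005 for `beta`).  A `single_rate` variant
with one shared learning rate is included.

Four experiment pipelines are provided: single-task evolution, multiple-task
evolution (four tasks per simulation, with the number of risk-seeking tasks
as the condition), an equal-expected-value **risk-tendency assay** of evolved
populations (two gain-domain and two loss-domain tasks), and a
`(alpha_p, alpha_n)` **parameter heatmap** at fixed `beta`.  Summary
statistics include risk-aversion rates, the Niv index
`(alpha_n - alpha_p) / (alpha_n + alpha_p)`, Cohen's *d* between the evolved
rates, the SD ratio, and the gain-minus-loss risk-aversion difference.

## Worked example

Evolve 500 agents for 500 generations on the risk-aversion task
N(10, 20) vs N(30, 5) (risky option pays 20 less on average):

```python
from evobandit import TaskSpec, run_evolution

res = run_evolution(TaskSpec(10, 20, 30, 5), n_agents=500,
                    n_generations=500, n_trials=200, seed=0)
last = res.trace.iloc[-1]
print(last[["mean_alpha_p", "mean_alpha_n", "mean_beta",
            "mean_risk_aversion_task1"]].round(3))
```

prints

```
mean_alpha_p                0.373
mean_alpha_n                0.510
mean_beta                   0.324
mean_risk_aversion_task1    0.989
```

The population learned to take the safe option almost always (risk aversion
0.989), and the negative learning rate evolved above the positive one
(`alpha_n > alpha_p`) — overweighting bad surprises makes agents abandon the
risky option quickly, which is exactly what pays in this environment.  In a
risk-seeking task the relationship inverts, with `alpha_n` collapsing toward
zero.

The same experiments are available from the shell, e.g.

```sh
evobandit single-task --task "N(10,20) vs N(30,5)" --scale desk --seed 1 --out results/ra
evobandit multi-task --condition 2 --scale desk --seed 1 --out results/mt2
evobandit heatmap --task "N(10,20) vs N(-10,5)" --seed 1 --out results/hm
```

Each run writes tidy CSV tables and a JSON manifest with the full
configuration and seed; see `docs/configuration.md` for config files and
scale presets (`paper`, `desk`, `smoke`).

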