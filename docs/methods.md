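# Methods

## Learning model

Agents are Rescorla-Wagner style learners on a two-armed bandit.  On each
trial the chosen option's value moves toward the received reward by a
fraction `alpha_p` of the prediction error when the error is non-negative
and `alpha_n` when it is negative; a zero prediction error is assigned to
the positive branch.  The unchosen option's value never changes, and values
restart at zero for every task an agent faces.  Choice is a two-option
softmax on the value difference with inverse temperature `beta`; `beta = 0`
is uniformly random choice, and larger values are greedier.  The
`single_rate` variant ties the two learning rates to one gene; it is
algebraically the asymmetric rule with `alpha_p = alpha_n`, and the
implementation reproduces it trial-for-trial, bit-for-bit.

Because learners only see the outcomes of chosen options and start from
zero values, two well-known forces shape behavior: an option abandoned
after a bad draw is rarely re-sampled ("hot stove" effect, amplified by
`alpha_n`), and positively located payoff distributions can trap an agent
in whichever option it happened to try first (amplified by `alpha_p` and
`beta`).

## Task environments

A task is a pair of normal payoff distributions; the risky option always
has the strictly larger SD.  The single-task grid crosses safe-option means
{-30, -20, -10, 0, 10, 20, 30} with risky-option SDs {10, 15, 20, 25, 30}
at a safe SD of 5, once with the risky mean `D = +20` above the safe mean
(risk-seeking tasks) and once `D = -20` below (risk-aversion tasks): 70
tasks, or 140 including the analogous `|D| = 10` grids.  This layout is a
reconstruction — it is consistent with every task named in the original
figures, and it is configurable so that a different grid can be swapped in.

Multiple-task environments are sets of four distinct tasks drawn uniformly
without replacement from the `|D| = 20` grid, constrained to contain a
prescribed number (0-4) of risk-seeking tasks; the drawing protocol is
likewise a reconstruction, isolated in one function.  Each set is
summarised by its *negative-area rate*: the mean of `Phi(-mu/sigma)` over
its eight option distributions, i.e. the average probability mass below
zero — a simple monotone proxy for how loss-like the environment is.

The risk-tendency assay uses four fixed equal-expected-value tasks,
N(20,20) vs N(20,5) and N(10,20) vs N(10,5) in the gain domain, N(-10,20)
vs N(-10,5) and N(-20,20) vs N(-20,5) in the loss domain.  Assay rates are
computed from the last 100 of 500 trials to exclude not-yet-learned early
behavior; evolutionary summaries use all trials.  Both windows are explicit
arguments, never implicit.

## Evolutionary procedure

Genes are initialized i.i.d. Uniform[0,1] (learning rates) and
Uniform[0,0.5] (`beta`).  Fitness is the arithmetic mean of every payoff an
agent collected across all tasks and trials of its generation plus a
baseline of 20; if the population minimum is negative, |min| + 0.1 is added
to everyone, making the minimum exactly 0.1.  Reproduction is roulette-wheel
sampling with replacement (N offspring, whole-generation replacement, no
elitism).  Mutation adds zero-mean Gaussian noise, SD 0.01 for the learning
rates and 0.005 for `beta`, read as (mean, SD) in line with the task
notation N(mu, sigma) used throughout.  "Truncated" is implemented by
rejection-resampling the noise until the gene is in range — a true
truncated-normal draw rather than clipping, which would pile probability
mass on the bounds.  Mutation applies to every offspring (no mutation-rate
parameter).  Per-generation summaries are recorded *before* selection, so
the first trace row describes the unevolved population; the returned final
population is the mutated offspring of the last recorded generation.

## Randomness and reproducibility

All randomness flows from one master seed through `numpy` `SeedSequence`
spawning: one child for initialization, one for the evolutionary draws
(selection and mutation), and one stream per agent slot for play.  Each
trial consumes one uniform (choice) and one standard normal (payoff, scaled
by the chosen option's mu and sigma); an agent's uniforms for a generation
are drawn before its normals.  The compiled population kernel consumes
exactly the same pre-drawn numbers, so batch execution is bit-identical to
per-agent sequential runs and every experiment is a pure function of
(configuration, seed).  The softmax exponent is clipped at ±700 so extreme
value differences saturate at probability 0/1 instead of overflowing.

## Scales

Experiments default to the full published scale (single-task: 10,000 agents
x 5,000 generations x 500 trials, 10 replicates; multiple-task: 1,000
agents, 100 simulations per condition).  The test suite and the acceptance
script use the `desk` scale as the package's working configuration:
single-task runs with 500 agents x 500 generations x 200 trials over 5
replicates, multiple-task runs with 200 agents x 300 generations x 200
trials per task and 10 simulations per condition (30 for the correlation
estimate, whose sampling error at 10 points would swamp the signal).  The
first-generation baseline uses 25 task sets per condition because
individual risk-seeking tasks span first-generation risk-aversion rates of
roughly 0.09-0.61 (SD ≈ 0.16 across the grid), so smaller samples cannot
resolve per-condition means to ±0.05.

## Known limitations

* Reduced-scale evolution is not fully converged.  With 300 generations the
  condition with a single risk-seeking task still carries `alpha_n` near
  0.5 (full-scale runs drive it below 0.32), and in risk-aversion
  single-task runs the mean `beta` is still rising at generation 500,
  sitting at the 0.35 boundary with considerable seed-to-seed spread
  (roughly 0.29-0.43 across replicates).  The negative-area/`alpha_p`
  correlation estimated from 30 reduced-scale simulations varies widely
  with the master seed (observed roughly 0.03-0.51).
* Tasks are stationary: payoff distributions never change within or across
  generations, and no foregone-payoff information exists.  Results say
  nothing about volatile environments or full-information learners.
* All inputs are synthetic by design — this is a simulation study; the
  generator *is* the studied system, so passing tests validate the model's
  internal claims, not any empirical data set.
* The heatmap uses a single 500-trial run per parameter cell by default
  (configurable repeats), so individual cells are noisy even though the
  regional structure is stable.
* Plots are not produced; all outputs are tidy CSV tables plus a JSON
  manifest.
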