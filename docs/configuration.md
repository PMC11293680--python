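# Run configuration

Experiments are configured by a YAML or JSON mapping passed to the CLI via
`--config` (or built from command-line options).  Unknown fields are
rejected by name; omitted size fields are filled from the scale preset.

## Fields

| field            | meaning                                                    | default |
|------------------|------------------------------------------------------------|---------|
| `experiment`     | `single_task`, `multiple_task`, `assay`, or `heatmap`      | required |
| `scale`          | size preset: `paper`, `desk`, or `smoke`                   | `paper` |
| `n_agents`       | population size N                                          | preset |
| `n_trials`       | trials per task per generation T                           | preset |
| `n_generations`  | generations G                                              | preset |
| `replicates`     | independent runs (single-task) / simulations (multi-task)  | preset |
| `n_risk_seeking` | risk-seeking tasks per four-task set (multi-task, assay)   | 2 |
| `variant`        | `asymmetric` or `single_rate`                              | `asymmetric` |
| `seed`           | master seed                                                | 0 |
| `out_dir`        | output directory                                           | `results` |
| `task`           | task label (single-task, heatmap)                          | — |
| `beta`           | fixed inverse temperature (heatmap)                        | 0.25 |
| `step`           | learning-rate grid step (heatmap)                          | 0.01 |
| `repeats`        | runs averaged per heatmap cell                             | 1 |
| `assay_window`   | final trials scored in the assay                           | 100 |

Scale presets:

| preset | single-task / heatmap            | multiple-task / assay           |
|--------|----------------------------------|---------------------------------|
| paper  | N=10,000 G=5,000 T=500, 10 reps  | N=1,000 G=5,000 T=500, 100 sims |
| desk   | N=500 G=500 T=200, 5 reps        | N=200 G=300 T=200, 10 sims      |
| smoke  | N=50 G=20 T=50, 2 reps           | N=50 G=20 T=50, 2 sims          |

## Annotated examples

Single-task evolution on a risk-aversion task, desk scale:

```yaml
experiment: single_task
task: "N(10,20) vs N(30,5)"   # risky option first, always
scale: desk
seed: 7
out_dir: results/ra
```

Multiple-task evolution, two risk-seeking tasks per set:

```yaml
experiment: multiple_task
n_risk_seeking: 2
scale: desk
replicates: 30                # override one preset field
seed: 7
```

Risk-tendency assay of populations evolved under the same protocol:

```yaml
experiment: assay
n_risk_seeking: 2
variant: single_rate          # one shared learning rate
scale: desk
seed: 7
```

Parameter heatmap of a risk-seeking task:

```yaml
experiment: heatmap
task: "N(10,20) vs N(-10,5)"
beta: 0.25
step: 0.01                    # 101 x 101 grid
seed: 7
```

## Outputs

Every run writes CSV tables (`summary`, `traces`, `final_populations`,
`task_sets`, `assay`, or `heatmap` as applicable) and a `manifest.json`
echoing the full configuration, master seed, package version, and file
inventory.  Re-running with the same configuration and seed reproduces the
CSVs byte-for-byte; only the manifest timestamp differs.
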