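# cadencelab

Cadence-based digital biomarkers and recovery-trajectory modelling for
minute-level wearable step streams, aimed at hip/knee arthroplasty
rehabilitation monitoring.

The pipeline extracts per-day biomarkers from minute-resolution step counts —
daily steps, the peak 1-minute cadence (highest step count in any single
minute), the peak 6-minute consecutive cadence (highest mean cadence over any
6-minute sliding window), and cadence-band intensity minutes — after removing
implausible minutes (> 150 steps/min). Downstream it quantifies intraweek
variability (coefficient of variation per surgery-anchored week), stratifies
patients by whether their Forgotten Joint Score gain at 3 months reaches the
surgery-specific minimal clinically important difference (17.5 hip total,
16.6 knee total, 12.5 unicondylar), and fits a random-intercept linear mixed
model (maximum likelihood) to baseline-normalized daily outcomes to estimate

- **return day** — the earliest post-operative day a group's modelled
  trajectory reaches its pre-operative reference level (parametric-bootstrap
  95% CI), and
- **separation day** — the earliest day the Wald 95% CI of the group contrast
  `b2 + b3*t` excludes zero.

A synthetic-cohort generator with analytically known ground truth (recovery
curves, crossing days, slope gaps) stands in for clinical data and drives the
verification suite.

## Layout

| Module | Role |
| --- | --- |
| `cadencelab.stream_model` | minute-stream / metadata / day-summary types and CSV I/O, surgery-day alignment |
| `cadencelab.biomarkers` | outlier removal, daily steps, P1M, P6MC, intensity minutes, weekly aggregation |
| `cadencelab.variability` | intraweek CV per patient and cohort-level weekly profiles |
| `cadencelab.stratification` | MCID thresholds and recovery labelling |
| `cadencelab.trajectory_model` | baseline normalization, mixed-model fit, diagnostics, return/separation days |
| `cadencelab.synthetic_cohort` | bout-based minute-stream generator with known truth |
| `cadencelab.cli` | `simulate` / `summarize` / `analyze` subcommands |

## CLI

```sh
# 1. generate a synthetic cohort (minute CSV, metadata CSV, truth JSON)
cadencelab simulate --config config.yaml --out out/sim

# 2. per patient-day biomarkers
cadencelab summarize --minutes out/sim/minutes.csv \
    --metadata out/sim/metadata.csv --out out/sum

# 3. variability + stratification + trajectory-model report
cadencelab analyze --summaries out/sum/day_summaries.csv \
    --metadata out/sim/metadata.csv --config config.yaml \
    --seed 1 --out out/analysis
```

A config file is YAML; generator keys mirror `GeneratorParams`
(`n_per_group`, `postop_days`, `recovery_timescale`, `steps_noise_cv`, ...),
intensity thresholds live under `thresholds:`, and analysis options
(`outcomes`, `n_boot`, `min_cv_days`) under `analysis:`. Every artifact embeds
the tool version, a config hash and the seed; identical config + seed gives
byte-identical outputs. Exit codes: 0 success, 1 user error, 2 model
non-convergence.

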