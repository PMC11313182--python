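# momentum-rpe

Momentum-biased reward-prediction-error (RPE) analysis pipeline for a
probabilistic Roulette task, built entirely on synthetic data with known
ground truth.

The package simulates a balanced two-group fMRI study and runs the full
model-based analysis chain:

1. **`task_design`** — pseudorandomized, exactly balanced trial schedules
   (8 blocks x 34 trials; win probability 25%/75% crossed with stakes 3/9;
   exact-frequency outcomes) with BIDS-style events TSV I/O.
2. **`rpe_models`** — unbiased RPEs, the recursive momentum-bias model
   (momentum `h` distorts perceived outcomes, which feed back into `h`),
   the difference modulator `Delta = biased - unbiased`, and two reduced
   confirmatory models (lag-1 carryover, momentum-only accumulator).
3. **`synthetic_bold`** — canonical double-gamma HRF, per-participant ROI
   BOLD for ventral striatum and left/right anterior insula with
   configurable ground-truth tracking and momentum-modulated
   insular-striatal coupling, AR(1) noise, drift, 6-parameter motion files,
   and two-group cohorts calibrated to published effect sizes.
4. **`first_level_glm`** — the 11-regressor first-level design (3
   conditions, 2 mean-centered parametric modulators at outcome, 6 motion
   parameters), OLS per run with drift nuisance, run-averaged contrasts.
5. **`ppi`** — generalized psychophysiological interaction at the BOLD
   level (centered seed x centered psychological regressor) with task
   conditions as covariates; specificity variant using the unbiased RPE.
6. **`group_stats`** — one-sample/two-sample/Welch t, Cohen's d, Pearson
   chi-square, standardized symptom regressions with optional log1p,
   Bonferroni correction; explicit tail conventions.
7. **`pipeline` / `cli`** — config-driven end-to-end run with a TSV report
   and a reproducibility manifest.

## CLI

```bash
momentum-rpe simulate-task --seed 1 --out events.tsv
momentum-rpe compute-rpes --events events.tsv --eta 0.3 --bias-weight 0.5 --out trace.tsv
momentum-rpe simulate-cohort --n-per-group 21 --seed 1 --out cohort/
momentum-rpe fit-first-level --cohort cohort/ --variant rpe --out contrasts.tsv
momentum-rpe ppi --cohort cohort/ --psych momentum-bias --out ppi.tsv
momentum-rpe group --contrasts contrasts.tsv --out group.tsv
momentum-rpe run --config config.yaml --out report/   # full pipeline
```

`momentum-rpe run` works without a config (all defaults); the YAML config
mirrors `PipelineConfig` (keys: `seed`, `n_per_group`, `schedule`, `model`,
`sim`, `effects`, `alpha`, `write_data`).

## Notes

- Model parameters (`eta`, `bias_weight`) are pipeline configuration with
  documented placeholder defaults; no per-participant fitting is performed.
- All outputs are plain text (TSV/JSON/YAML); cohorts round-trip through
  `write_cohort`/`read_cohort` bit-exactly.
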