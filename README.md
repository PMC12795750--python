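# noisequity

Cumulative noise-inequity analysis at census-tract scale, exercised
end-to-end on a seeded synthetic census-geography generator with recorded
ground truth.

The pipeline estimates, for every tract:

- **workplace noise prevalence** — Monte Carlo share of workers whose 8-h
  TWA noise exceeds 85 dBA, from employment counts by major occupational
  group and a job-exposure matrix (per-group normal mean/SD on the dBA
  scale); tracts with ≤20 workers are excluded;
- **transportation noise prevalence** — population-weighted Monte Carlo
  share of residents in census blocks whose 24-h L_Aeq exceeds 55 dBA;
  tracts with ≤20 residents are excluded;

and then computes:

- **exposure-risk ratios** (workplace, transportation, and cumulative —
  the product of the two prevalences) by racial/ethnic group, with
  tract-resampling bootstrap CIs (50th / 2.5th / 97.5th percentiles);
- **cumulative-high classification** — tracts above the 75th percentile of
  both prevalence distributions;
- **structural-racism indices** — the historical redlining score (HRS,
  area-weighted HOLC grade in [1, 4], requiring ≥20% graded overlap) and
  the mortgage-discrimination index D (minority loan share over minority
  household share; D < 1 = sustained discrimination);
- **regression stages** — logistic (cumulative-high), Poisson with
  log-denominator offsets (each prevalence), and linear (average prevalence
  against HRS, stratified by sustained discrimination), with
  metro-stratum-specific quintile exposures, a natural spline of log
  population density (8 df), a 4×5 tensor-product smooth of the tract
  centroid (20 df), and an SES sensitivity variant.

## CLI

```sh
noisequity run-all --config examples/demo.yaml --out scratch/demo
noisequity validate --out scratch/demo
```

Stages can also be run individually (`generate`, `prevalence`, `metrics`,
`indices`, `models`) against the same run directory. Every run writes CSV
stage outputs, a Markdown report, and a `manifest.json` with the config
hash, seed and per-file row counts/hashes; identical config+seed gives
identical manifests.

## Layout

- `src/noisequity/synthetic_data.py` — seeded generator for tract, block,
  JEM, HOLC-overlap and mortgage tables; records ground-truth effect sizes
  (never consumed by analysis stages)
- `src/noisequity/workplace_noise.py` — JEM exceedance and tract workplace
  prevalence Monte Carlo
- `src/noisequity/transportation_noise.py` — block-to-tract aggregation and
  county/metro/nationwide exposed-count aggregation
- `src/noisequity/inequity_metrics.py` — ERRs, bootstrap, cumulative-high
  flags, quintiles
- `src/noisequity/structural_racism.py` — HRS, D index, sustained flag
- `src/noisequity/regression_models.py` — design construction and the three
  GLM families plus the SES sensitivity refit
- `src/noisequity/pipeline.py`, `cli.py` — orchestration, validation, CLI
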