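# strokerisk

Absolute stroke-risk scoring and model validation at desk scale.

The package implements:

* **`strokerisk.risk_models`** — a Framingham-style base model (Cox linear
  predictor + baseline-survival transform, sex-specific coefficient sets)
  and an extended model that adds published risk deltas on top of it:
  additive log-hazard terms for lifestyle/ethnicity flags (0.20 non-Caucasian,
  0.20 poor diet, 0.10 high alcohol, 0.10 low physical activity, 0.05 family
  history), hazard-ratio multipliers entered as `ln(HR)` (1.80 cognitive
  problems, 1.40 memory-only, 1.20 previous TBI), an anthropometric fallback
  chain (waist-to-hip ratio → BMI → waist circumference), and an absolute
  +10 / +15 percentage-point addition for previous stroke/TIA at the 5- /
  10-year horizon, capped at 100%. Every risk estimate carries the matched
  no-risk-factor baseline for the same age and sex.
* **`strokerisk.discrimination`** — ROC curves, Mann–Whitney AUROC, DeLong
  variance/CI and the paired DeLong test for correlated AUROCs, Harrell's C
  with censoring, Somers' D (= 2C − 1), and Cox–Snell/Nagelkerke pseudo-R².
* **`strokerisk.calibration_classification`** — Hosmer–Lemeshow over risk
  deciles (with a df policy for fitted vs externally specified
  probabilities), calibration-by-decile points, confusion matrices at a
  threshold, accuracy-targeted threshold search, high/low classification
  with shipped default thresholds, and 2×2 model cross-tabulation.
* **`strokerisk.synthetic_cohorts`** — seeded synthetic cohorts from
  marginal specs (truncated-normal continuous variables, Bernoulli flags)
  with outcomes drawn either from a risk model (calibration-faithful binary
  or exponential event-time simulation) or at a constant null rate. Presets:
  `russia-like`, `rotterdam-like`, `arcos-like` (case-only).
* **`strokerisk.cli_io`** — cohort CSV and model-config JSON I/O, the
  validation-report orchestrator, and the `strokerisk` CLI.

The shipped default coefficient set (`strokerisk/data/default_model.json`)
is an approximate transcription of the published Framingham stroke
probability equations and is labelled as such in its `provenance` field;
all exactness tests use toy coefficient sets, so nothing in the test suite
depends on that transcription.

## CLI

```sh
# simulate a cohort whose outcomes are drawn from the model itself
strokerisk simulate --preset rotterdam-like --n 2000 --seed 1 \
    --outcome model --out cohort.csv

# score it (add --out risks.csv for per-row output)
strokerisk score --cohort cohort.csv --model riskometer --horizon 5

# full validation battery, sex-stratified, written to report/report.json
strokerisk validate --cohort cohort.csv --models fsrs,riskometer \
    --horizons 5,10 --out report

# paired DeLong comparison of two models
strokerisk compare --cohort cohort.csv --model-a riskometer --model-b fsrs
```

Custom models are JSON files with `{model_name, sex_specific: {male, female},
deltas}`; see `src/strokerisk/data/default_model.json` for the schema. A
QStroke-style comparator can be supplied the same way.

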