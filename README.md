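# crval

Evaluation and external-validation toolkit for two-cause competing-risks
prognostic models on registry-style survival cohorts.

The package covers the full validation workflow for a coefficient-driven
prognostic model that predicts, per patient, 15-year cancer-specific
mortality, other-cause mortality and all-cause mortality:

- **`crval.cohort`** — patient-level domain types, inclusion/exclusion
  filtering with a per-reason exclusion log, treatment-group assignment
  (conservative / radical / ADT) and cohort summary statistics (crude
  mortality rates per 100 person-years, 10-year truncated event counts).
- **`crval.synthetic`** — registry-like synthetic cohorts: covariates from
  configurable marginals, outcomes from two latent piecewise-exponential
  cause-specific clocks driven by the same hazards the risk engine
  evaluates, staggered accrual and administrative censoring. Every
  downstream stage is testable against this generative truth.
- **`crval.engine`** — the risk engine: prognostic indices from declared
  covariate transforms, annual baseline hazards, the exact
  piecewise-constant competing-risks decomposition (CIF per cause +
  overall survival, conserving to machine precision), treatment scenarios
  (as-treated / conservative / radical) and expected event counts over
  each patient's available follow-up.
- **`crval.comparators`** — ordinal comparator classifiers (CAPRA-style
  points, EAU-style 3-stratum, NCCN-style 4-stratum) from versioned JSON
  schedules, with the T2→T2a and unknown-PPC→low-band imputations.
- **`crval.validation`** — Harrell's c-index with jackknife SE/CI and
  paired score comparisons, observed:expected calibration ratios,
  quintile calibration with a grouped chi-square goodness-of-fit, and
  subgroup calibration tables, assembled into one report object.
- **`crval.pipeline` / `crval.cli`** — end-to-end orchestration with a
  reproducibility log, exposed as the `crval` command.

## CLI

```bash
# generate a benchmark synthetic cohort (CSV) and its generative truth
crval simulate --n 20000 --seed 1 --out cohort.csv --truth-out truth.json

# apply inclusion criteria; prints the exclusion log summary
crval filter --cohort cohort.csv --out filtered.csv

# per-patient annual estimates under all treatment scenarios
crval predict --cohort filtered.csv --coeffs truth.json --out predictions.csv

# comparator risk-group labels
crval classify --cohort filtered.csv --system capra --out labels.csv

# discrimination + calibration report bundle (JSON + CSV views)
crval validate --cohort filtered.csv --coeffs truth.json --out report/

# full pipeline from one config
crval run --seed 1 --out run_out/
```

Coefficients are configuration (JSON schema documented in
`crval.engine.CoefficientSet`); the bundled default set is illustrative
only and is not fitted to any data. Cohort CSV columns are documented in
`crval.io`.

## Notes on conventions

- Crude rates are events per 100 person-years to two decimals.
- Expected event counts default to the integrated cause-specific hazard
  over observed at-risk time (the counting-process compensator), which is
  the convention under which observed equals expected on data generated
  by the model itself; a CIF-at-exit-time variant is available via
  `expected_events(..., method="cif")` for sensitivity analyses.
- The goodness-of-fit statistic is the grouped `sum (O-E)^2 / E` with
  `G - 1` degrees of freedom (configurable); risk groups are ranked by
  fixed-horizon predicted risk with ties broken by stable input order.
- Subgroup percent differences are `100 * |E - O| / O` to one decimal;
  the convention is recorded in every report.
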