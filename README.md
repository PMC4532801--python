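# vernaltherm

Vernalization thermal-response analysis for flowering-time experiments:

- **climate_io** — read/validate temperature and snow-depth records (hourly
  logger traces or thrice-daily 0600/1200/1800 station readings), build daily
  means, compute autumn-window statistics (1 Aug–30 Nov by default), and
  detect snow cover from the clamped soil-surface temperature signature.
- **accumulator** — accumulate vernalization-effective time under a
  configurable open temperature window, on an hourly or daily-mean basis
  (e.g. the legacy (0, 6) °C hourly window vs a (0, 15) °C daily-mean
  window), expressed in 168-hour effective weeks against a constant-reference
  accumulation line.
- **response_surface** — fit genotype flowering-time response surfaces over a
  (constant temperature × cold duration) cabinet grid, with DNF
  (did-not-flower) censoring carried as a per-cell proportion; query by
  bilinear interpolation; derive the optimum temperature and the effective
  temperature range.
- **field_predictor** — predict flowering of field transplant cohorts by
  matching the sow→transfer interval mean temperature and duration to the
  nearest cabinet condition (or by interpolation), and summarize residuals.
- **synthetic_data** — generate autumn weather traces (linear seasonal trend
  + diurnal cycle + AR(1) noise + optional snow clamp) and flowering-time
  datasets from a parametric ground-truth response model, so that every
  stage is testable offline against known parameters.
- **assay_norm** — expression normalization to a reference gene and the
  ChIP (mark/H3 target) / (mark/H3 control) double ratio, with a paired
  per-primer profile comparison.

## CLI

```sh
vernaltherm summarize-autumn --input temps.csv --season 08-01:11-30 --window 0:15
vernaltherm accumulate --input temps.csv --window 0:6 --basis hourly --reference 8 --out trace.csv
vernaltherm fit-surface --input flowering.csv --out surface.csv
vernaltherm query --surface surface.csv --temp 8 --weeks 6
vernaltherm predict-field --surface surface.csv --temps field_temps.csv \
    --cohorts cohorts.csv --mode match --out predictions.csv
vernaltherm simulate --config sim.yaml --out-dir fixtures/
```

Temperature CSVs carry `timestamp` (ISO 8601, local civil time), `temp_c`
and optionally `snow_depth_cm`. Flowering CSVs carry `genotype`, `temp_c`,
`duration_weeks`, `replicate_id`, `days_to_flower`, `dnf`. Cohort CSVs carry
`genotype`, `sow_date`, `transfer_date`, `replicate_id`, `days_to_flower`,
`dnf`.

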