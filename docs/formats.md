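# File formats

All interchange is plain CSV / JSON / YAML. Times are seconds from trip
start; depths are metres, positive downward.

## Inputs

* `depth_<id>.csv` — `time_s, depth_m`; uniform 1-s grid.
* `accel_<id>.csv` — `time_s, ax, ay`; uniform grid at the sensor rate
  (16 Hz default). `ax` is the horizontal jaw channel used for detection.
* `nights.json` — `{ "<id>": [[start_s, end_s], ...], ... }` night windows
  per individual (required when running from files rather than simulation).
* `config.yaml` — serialized `PipelineConfig`; every analysis threshold
  with its default (3-m dive, 15-m deep, 0.4 m/s rate, 8-s step cap, 3-s
  wiggle gap, 60 % depth fraction, 85 % coverage, 0.95 weight threshold,
  3-Hz cutoff, 1.5-s / 5-s windows, robust threshold k = 6).

## Per-run artifacts (written by `foragedive run` / `run_pipeline`)

* `dives.csv` — one row per detected dive: identity, timing, phase
  durations and rates, feature counts, `bout_id`, `included`, `pca_count`.
* `bout_criteria.json` — the fitted surface-interval mixture per
  individual: BEC (s), fast/slow process means, mixing proportion.
* `truth_<id>.json` — simulation ground truth (simulated runs only).
* `table_<scale>.csv` — raw (unstandardized) predictor/response table,
  `<scale>` in `dive, bout, win30, win60, win120, night`.
* `models_<scale>.csv` — ranked enumeration: `predictors, logLik, k, AICc,
  delta, weight, cum_weight`.
* `averaged_<scale>.csv` — model-averaged coefficients: `predictor, w
  (importance), coef, se` with the intercept first.
* `cv_folds_<scale>.csv` — `individual_id, n, c_index` per held-out fold.
* `cv_scatter_<scale>.csv` — `individual_id, observed, predicted` for
  observed-vs-predicted plots.
* `manifest.json` — seed, config hash, package version, per-stage counts
  (dives detected / deep / included, events, models fitted, C-indices).

Exit codes of the CLI: 0 ok, 2 configuration error, 3 data error.
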