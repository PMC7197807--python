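# iokinetics

A five-compartment biokinetic model of orally administered radioiodine
(I-131) and the analysis pipeline around it:

- **model_core** — the linear compartment system (stomach → body fluid →
  thyroid → whole body, whole-body → body-fluid feedback, excretion sink)
  solved exactly by matrix exponential and independently by a fixed-step
  RK4 oracle; effective-half-life combination; shipped reference-adult and
  nine-patient parameter sets.
- **observation** — mapping trajectories to the three gamma-scan ROIs
  (St, Th, BF+WB), background subtraction, normalization to the first
  stomach scan, and the RMS agreement index (per-ROI and total).
- **fitting** — per-patient estimation of the four free parameters
  (stomach, shared BF/WB and thyroid half-lives, branching fraction i23)
  by bounded grid search plus Nelder-Mead refinement minimizing the total
  agreement index; cohort mean ± sample-SD summaries.
- **synthetic** — reproducible synthetic scan cohorts (model curves with
  per-patient gain, multiplicative noise, and flat background) for
  end-to-end testing and parameter-recovery studies.
- **io / cli** — measurement CSV and parameter/result JSON readers and
  writers, and a `click` command-line interface.

## CLI

```bash
# synthetic cohort (measurements.csv + truth.json)
iokinetics generate --output out/gen --n-patients 9 --noise-cov 0.05 --seed 1

# fit every patient and summarize the cohort
iokinetics fit --input out/gen/measurements.csv --output out/fits

# trajectory + ROI curves for given (or default cohort-average) parameters
iokinetics simulate --output out/curves.csv

# agreement report for data against fixed parameters
iokinetics at --input out/gen/measurements.csv --params params.json

# cohort statistics from a fitted cohort CSV
iokinetics summarize --input out/fits/cohort.csv
```

A JSON config file (`--config`) can mirror any flag; explicit flags win.

## Measurement CSV dialect

Header `patient_id,time_h,roi,value_counts_per_pixel_per_s`, one row per
(patient, time, ROI). ROI labels: `St`, `Th`, `BFWB`, optional `BKG`
(background, subtracted before normalization) and `Bl` (accepted,
ignored). Default scan schedule: 1, 4, 24, 48, 72, 168 h.

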