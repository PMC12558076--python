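# lesionkinetics

Volumetric tumor-burden kinetics for serially imaged lesions: ellipsoid
volumetry from tri-planar diameter measurements, exponential growth-constant
and tumor-growth-rate (TGR) estimation, progression classification, and the
downstream cohort statistics — grouped baseline summaries, Mann–Whitney and
Fisher exact comparisons, Kaplan–Meier time-to-event curves with Greenwood
variance, and a logistic progression model with listwise deletion. A seeded
synthetic-cohort generator makes every stage testable without patient data.

## Method summary

- A lesion measured in the transverse, coronal and sagittal planes is treated
  as an ellipsoid with semi-axes equal to half the planar diameters:
  `V = (pi/6) * d1 * d2 * d3` (mm³).
- Growth between baseline volume `V1` and the most recent follow-up `V2`
  over `t` months is modeled as `V2 = V1 * exp(g * t)`, so
  `g = ln(V2/V1) / t` and `TGR = 100 * (exp(g) - 1)` in % per month.
  A month is 30.4375 days; follow-ups shorter than 2 months are excluded.
- Progression means a strict volume increase (`delta_v > 0`, i.e. `TGR > 0`).

## Command-line usage

```sh
# generate a synthetic cohort (lesions.csv + patients.csv)
lesionkinetics simulate --seed 1 --out-dir cohort/

# per-patient growth constants and TGR from serial measurements
lesionkinetics tgr cohort/lesions.csv -o growth.csv

# individual report tables
lesionkinetics summarize cohort/lesions.csv cohort/patients.csv
lesionkinetics km cohort/lesions.csv cohort/patients.csv --endpoint os -o km_os.csv
lesionkinetics logit cohort/lesions.csv cohort/patients.csv
lesionkinetics compare-prrt cohort/lesions.csv cohort/patients.csv
lesionkinetics locations cohort/lesions.csv cohort/patients.csv

# everything at once (growth, summary, logistic, PRRT, locations, two KM curves)
lesionkinetics full cohort/lesions.csv cohort/patients.csv -o reports/
```

Exit codes: 0 success, 2 input-validation failure, 3 analysis failure.
Input schemas (CSV, header row, ISO-8601 dates, 0/1 booleans, empty cell =
missing) are documented in `src/lesionkinetics/io.py`.

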