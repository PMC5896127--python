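# File formats

## Episode records

### JSON

One document holding a list of episode objects (a single object is also
accepted). The machine-readable schema is in
[`episode_schema.json`](episode_schema.json). Dates are ISO-8601. Minimal
example:

```json
[
  {
    "patient_id": "p1",
    "onset_date": "2019-06-01",
    "assessment_date": "2020-06-01",
    "baseline_severity": {"instrument": "HRSD17", "score": 22,
                          "psychotic_features": false},
    "trials": [
      {"drug_name": "fluoxetine", "dose_mg_per_day": 20,
       "duration_weeks": 8, "adherent": true, "tolerated": true,
       "outcome": "no_response"}
    ],
    "augmentations": [{"agent_name": "lithium", "used": true}],
    "ect": {"n_sessions": 8, "completed": true, "outcome": "no_response"}
  }
]
```

### CSV (header + trials sidecar)

Two files: an episode-header CSV (one row per episode) and a trials sidecar
(one row per trial, keyed by `patient_id`). The sidecar defaults to the
header file's name with `.csv` replaced by `.trials.csv`.

`episodes.csv` columns: `patient_id, onset_date, assessment_date,
is_first_episode, baseline_instrument, baseline_score, baseline_psychotic,
augmentations` (semicolon-separated agent names), `ect_n_sessions,
ect_completed, ect_outcome` (ECT columns blank when no course was given).

`episodes.trials.csv` columns: `patient_id, drug_name, dose_mg_per_day,
duration_weeks, start_date, end_date, adherent, tolerated, outcome,
outcome_instrument, outcome_score`.

## Dose table

YAML mapping or CSV with columns `drug_name, min_effective_dose_mg`:

```yaml
fluoxetine: 20
sertraline: 50
venlafaxine: 75
```

## Severity threshold tables

CSV with columns `instrument, category, lo, hi` (inclusive integer bounds;
categories: remission, subthreshold, mild, moderate, severe, very_severe).
Dump the built-ins with `msm thresholds --out thresholds.csv`; validate a
custom table with `msm thresholds --check mytable.csv`.

## Reports

`write_report` emits JSON, CSV, or a text worksheet. JSON and CSV carry
identical fields: `patient_id, status, total, band,
treatment_failure_score, severity_score, duration_score,
n_failed_antidepressants, augmentation_used, ect_used,
pseudo_resistance_flags` (semicolon-joined) and `adjudications`
(`index:verdict:reason`, pipe-joined). Score columns are empty for
not-treatment-resistant episodes.
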