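# msm-staging

Scoring library and CLI for the **Maudsley Staging Method (MSM)**, a
dimensional staging instrument for treatment-resistant depression (TRD).
It is written for clinical researchers and tertiary-care services who need
a replicable, auditable way to turn a patient's treatment history into a
resistance stage — including the unglamorous parts: deciding which
antidepressant trials were *adequate*, screening for pseudo-resistance,
and dating the presenting episode.

## The score

TRD is modelled as a continuum starting at the first failure of an
adequately given antidepressant. An episode is staged on three dimensions:

| Dimension | Score | Rule |
|---|---|---|
| Treatment failure | 1–7 | failure level (1–2 → 1, 3–4 → 2, 5–6 → 3, 7–10 → 4, >10 → 5) + 1 if augmentation used + 1 if ECT course ≥ 8 sessions |
| Symptom severity | 1–5 | subsyndromal 1, mild 2, moderate 3, severe 4, severe with psychosis 5 |
| Episode duration | 1–3 | acute ≤ 12 months 1, sub-acute 13–24 months 2, chronic > 24 months 3 |

Total = sum ∈ [3, 15]; bands **mild 3–6**, **moderate 7–10**, **severe
11–15**. A trial counts as a failure only if it was adequate — minimum
effective dose, ≥ 6 weeks (4 in research mode), adherent, tolerated — and
did not reach clinical remission (e.g. HRSD17 ≤ 7); a response short of
remission still counts. Inadequate trials are excluded and flagged as
pseudo-resistance instead. Severity is read from any of HRSD17, QIDS-C16,
QIDS-SR16, IDS-C, IDS-SR, CGI, PSR or an ICD-10/DSM checklist through
built-in threshold tables (overridable; see `docs/methods.md`).

## Worked example

Four adequately-given failed antidepressants, lithium augmentation, no ECT,
baseline HRSD17 = 22 without psychotic features, 18-month episode
(`examples/stage_single_episode.py`):

```
=== MSM staging: patient example-001 ===
Dimension 1  treatment failure : 3  (4 failed antidepressant(s), augmentation yes, ECT no)
Dimension 2  symptom severity  : 3
Dimension 3  episode duration  : 2
TOTAL (3-15)                   : 8   band: MODERATE
```

Four failures put the patient at failure level 2; augmentation adds 1
(dimension 1 = 3). HRSD17 22 falls in the moderate interval 20–25
(dimension 2 = 3), and 18 months is sub-acute (dimension 3 = 2): total 8,
moderate resistance. The other scripts in `examples/` demonstrate
pseudo-resistance screening, synthetic cohorts and episode merging.

## Command line

```bash
msm stage --input episodes.json --dose-table doses.yaml --out report.csv --strict
msm validate --input episodes.csv
msm thresholds --out thresholds.csv
msm synth --n 100 --seed 42 --out cohort.json
```

Input formats (JSON; CSV with a trials sidecar) and report formats are
documented in `docs/formats.md`. `--strict` exits with code 2 on any
invalid record.

## Layout

- `src/msm_staging/` — `model` (record types, validation), `adequacy`
  (trial adjudication), `severity_map` (threshold tables), `duration`
  (dating/merging), `stager` (score assembly), `synth` (cohort generator),
  `io`/`cli` (files and the `msm` command).
- `docs/methods.md` — model, assumptions, parameter defaults, limitations.
- `examples/` — one short runnable script per capability.
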