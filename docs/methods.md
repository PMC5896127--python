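# Methods

## The staging model

`msm_staging` implements the Maudsley Staging Method (MSM), a dimensional
staging score for treatment-resistant depression (TRD). TRD is treated as a
continuum rather than an all-or-nothing label: its onset is the failure of
the first adequately given antidepressant, and its stage is the sum of
three dimension scores rated for the *presenting* episode:

| Dimension | Range | Rated from |
|---|---|---|
| 1. Treatment failure | 1–7 | adjudicated antidepressant failures + augmentation + ECT |
| 2. Symptom severity at baseline | 1–5 | instrument score + psychotic-features flag |
| 3. Episode duration | 1–3 | onset → assessment dates |

Total = D1 + D2 + D3 ∈ [3, 15]; bands: mild 3–6, moderate 7–10, severe
11–15. The band is a function of the total only; no dimension overrides it.

Dimension 1 decomposes as an antidepressant-failure *level* (1–2 failures →
1, 3–4 → 2, 5–6 → 3, 7–10 → 4, >10 → 5) plus two binary indicators:
augmentation used (+1) and a qualifying ECT course (+1), maximum 7.
The indicators score on *delivery* — any documented augmentation use, and
an ECT course of at least `ect_min_sessions` (default 8) regardless of its
outcome — because the scale rates exposure, not a second failure count.
A failed ECT course never increments the antidepressant tally; the two are
scored in separate slots by construction.

An episode with **zero counted failures** returns an explicit
`NotTreatmentResistant` status instead of a score: the scale starts at 3
and presupposes at least one adequate failure. A baseline assessment in the
remission interval raises `StagingRefusedError` — there is no current
syndromal or subsyndromal episode to stage.

## Trial adequacy and pseudo-resistance

A trial counts toward dimension 1 only if all four gates pass:

1. **dose** ≥ the drug's minimum effective daily dose (configurable table);
2. **duration** ≥ 6 weeks, or 4 weeks with `research_mode_four_weeks=True`
   (the early-detection research convention);
3. **adherent** for substantially the whole trial;
4. **tolerated** (not stopped for side effects).

Failure = failure to reach clinical remission; a response short of
remission still counts as a failure. Remission is read from the
end-of-trial instrument score when one is recorded (this overrides the
categorical outcome field), otherwise from the categorical outcome. An
adequate trial with outcome `unknown` and no score is adjudicated
*inadequate (unratable)* rather than silently counted as a failure.
Distinct courses of the same drug count separately; each antidepressant in
a combination is entered as its own trial and counts if individually
adequate. Augmentation agents never enter the antidepressant tally.

Gates that fail aggregate into pseudo-resistance flags (`inadequate_dose`,
`inadequate_duration`, `non_adherence`, `intolerance`) — a screening aid:
a history full of inadequate trials suggests apparent rather than true
resistance.

**Dose table.** Minimum effective doses are configuration, not clinical
fact baked into code. The starter table covers 22 commonly prescribed
antidepressants with conventional guideline minimums (e.g. fluoxetine
20 mg, sertraline 50 mg, venlafaxine 75 mg, amitriptyline 75 mg); sites
should review and override it via YAML/CSV (`--dose-table`). An unknown
drug raises `UnknownDrugError` rather than passing silently.

**Remission duration rule.** Default `single_measure`: one remission-status
measure over the instrument's time frame suffices. The stricter
`sustained_two_months` rule additionally requires a confirmatory remission
measure ≥ 60 days after the first (carried in the trial's
`confirmatory_outcome` field); when only one dated measure exists the rule
degrades to `single_measure` with a logged warning instead of failing.

## Severity mapping

Instrument totals map to six ordered clinical-status categories (remission,
subthreshold, mild, moderate, severe, very_severe) via per-instrument
interval tables, then to the MSM severity score: subthreshold → 1, mild →
2, moderate → 3, severe → 4, **very_severe → 4**. Level 5 is reserved for
psychotic depression: `psychotic_features=True` forces 5 regardless of the
scale total, so the psychosis flag is a required input, not an inference
from score magnitude. ICD-10/DSM checklist ratings bypass the interval
tables: their ordinal category 1–5 is the severity score directly.

Built-in tables (version `builtin-1`): HRSD17 0–7 / 8–13 / 14–19 / 20–25 /
26–52; QIDS-C16 and QIDS-SR16 0–5 / 6–10 / 11–15 / 16–20 / 21–27; IDS-C
0–11 / 12–23 / 24–36 / 37–46 / 47–84; IDS-SR 0–13 / 14–25 / 26–38 / 39–48 /
49–84; CGI 1 / 2 / 3 / 4 / 5–6 / 7; PSR 1–2 / 3 / 4 / 5 / 6 / 7. Where an
instrument publishes five bands against the six categories, the bands fill
remission…severe and `very_severe` is left unpopulated — harmless for
staging since severe and very_severe share score 4, and a custom table may
split the top interval. The published MADRS band alignment is ambiguous, so
MADRS is **disabled** until an explicit table is supplied. Tables are
validated on load (sorted, contiguous, gap-free, covering the admissible
range) and every integer score is checked exhaustively in the tests.
Scores must be integers; non-integers are rejected, never rounded — a
fractional total is a data error upstream.

## Episode dating, duration, merging

Duration is `(assessment_date − onset_date) / 30.44` days-per-month
(mean Gregorian month), including any pre-treatment period. Onset is the
full-episode onset for first episodes and the prodromal-symptom onset for
relapse episodes; prodrome detection is out of scope — the date is an
input. Categories: acute ≤ 12 months (1), sub-acute (12, 24] (2), chronic
> 24 (3). The two published boundary conventions differ only at exactly 12
and 24 months; the default follows the scored convention (closed on the
left category), and `table5_convention=True` flips to half-open
[0,12) / [12,24) / [24,∞).

Apparent episodes separated by a remission gap shorter than
`separation_months` (default 2) are merged — onset of the first, assessment
of the last, trials concatenated so continuation-period failures count
together. Gaps ≥ 2 months keep episodes distinct (each gets its own
record and rating). Merging is idempotent; overlapping episodes are an
error. When both halves carry an ECT course the larger course is kept,
since only the binary indicator is scored; the first episode's baseline
severity and first-episode flag are retained.

## Record model and validation

Records are pydantic models; type/shape errors fail at parse time, while
domain invariants (score ranges, date ordering, non-negative doses) are
checked by `validate_episode`, which returns a list of issues with dotted
field paths instead of raising — retrospective treatment histories are
imperfect and should be inspectable, not rejected wholesale. A trial may
carry explicit dates, a `duration_weeks`, or both; dates are authoritative
and a disagreement of more than one week is flagged.

## Synthetic cohorts

`generate_cohort(n, seed, profile)` emits records with the structure a
treatment-history inventory yields, driven by one `numpy` generator
(byte-identical output for a given seed). The default profile sketches a
tertiary-care TRD population: failure counts truncated-geometric over 1–15
(p = 0.35, so mostly 1–4 failures), augmentation in ~30%, ECT in ~10%,
psychotic features in ~10%, baseline severity drawn uniformly over levels
1–4 on a mix of HRSD17/QIDS-C16/PSR/CGI, episode duration log-normal with
median ≈ 12 months, and a 10% rate of each deliberately inadequate trial
kind (under-dosed, 3-week, non-adherent) to exercise the pseudo-resistance
screen. These are plausibility choices for exercising the scorer, not
fitted epidemiology: the generator does not simulate treatment-response
dynamics, instrument measurement error, missing data, or correlations
between severity, duration and failure count — so passing tests demonstrate
correctness of the *scoring rules* on conformant records, not calibration
against any real cohort. Drug names come from the starter dose table so
every trial is adjudicable; dates are synthesized backward from a fixed
assessment date to hit target durations exactly.

`lattice_fixtures()` builds one minimal record per cell of the
antidepressant-level × augmentation × ECT × severity × duration lattice
(5·2·2·5·3 = 300) with representative failure counts {1, 3, 5, 7, 11} and
durations {6, 18, 30} months; the tests stage all 300 and compare against
independent per-dimension arithmetic decoded from each cell's label,
confirming the attainable totals are exactly {3,…,15}.

## Numerical and degenerate-input choices

- All scores and thresholds are integer arithmetic; the only real-valued
  quantities are durations (weeks, months), compared with plain `<`/`≤` at
  the stated boundaries.
- Month length 30.44 days; a 365-day episode is 11.99 months (acute), which
  is the intended reading of "a year and less".
- Empty trial list: validation passes, staging returns the
  not-treatment-resistant status.
- Zero-length episodes (onset = assessment) are legal: duration 0, acute.
- The adjudication trail indexes trials by position so reports remain
  auditable against the input record.

## Known limitations

- The severity tables are transcriptions of published conventions that are
  themselves acknowledged to be imperfect (QIDS remission cut-offs likely
  too permissive); they are data and should be re-examined per study.
- Relapse-episode onset dating (prodrome onset) is implemented as specified
  but its validity is untested in the literature this follows.
- No blood-level dose adequacy, no psychotherapy-failure rating, no
  functional-impairment or personality items, and no predictive modelling
  of outcomes from the score.
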