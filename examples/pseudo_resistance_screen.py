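"""Screen a treatment history for pseudo-resistance before staging.

Three apparent failures, but only one was an adequate trial: one course was
under-dosed and one was stopped in week 3. Only the adequate failure counts,
so the patient stages at the level for one failure, and the inadequate
trials surface as pseudo-resistance flags rather than inflating the score.
"""

from datetime import date

from msm_staging import (
    EpisodeRecord,
    Instrument,
    Outcome,
    SeverityAssessment,
    TreatmentTrial,
    adjudicate_episode,
    pseudo_resistance_flags,
    stage,
)

episode = EpisodeRecord(
    patient_id="example-002",
    onset_date=date(2019, 10, 1),
    assessment_date=date(2020, 6, 1),
    baseline_severity=SeverityAssessment(instrument=Instrument.QIDS_C16, score=17),
    trials=(
        TreatmentTrial(drug_name="citalopram", dose_mg_per_day=10,  # min is 20
                       duration_weeks=8, outcome=Outcome.NO_RESPONSE),
        TreatmentTrial(drug_name="sertraline", dose_mg_per_day=50,
                       duration_weeks=3, outcome=Outcome.NO_RESPONSE),
        TreatmentTrial(drug_name="venlafaxine", dose_mg_per_day=150,
                       duration_weeks=8, outcome=Outcome.RESPONDED_NOT_REMITTED),
    ),
)

for adj in adjudicate_episode(episode):
    print(f"trial {adj.trial_index} ({episode.trials[adj.trial_index].drug_name}): "
          f"{adj.verdict.value} — {adj.reason}")
print("pseudo-resistance flags:", [f.value for f in pseudo_resistance_flags(episode)])

result = stage(episode)
print(f"counted failures: {result.dimensions.n_failed_antidepressants} "
      f"→ treatment dimension {result.dimensions.treatment_failure_score}, "
      f"total {result.total} ({result.band.value})")
print("Only the adequate venlafaxine course counts; a response short of "
      "remission is still a failure.")
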