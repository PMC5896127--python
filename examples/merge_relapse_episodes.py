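"""Merge apparent episodes separated by a short remission.

Two recorded episodes one month apart are treated as one continuing illness
(remission gaps under two months do not separate episodes), so the failures
from both periods count together and the merged duration crosses into the
sub-acute band.
"""

from datetime import date

from msm_staging import (
    EpisodeRecord,
    Instrument,
    Outcome,
    SeverityAssessment,
    TreatmentTrial,
    episode_duration_months,
    merge_episodes,
    stage,
)


def _trial(drug, dose):
    return TreatmentTrial(drug_name=drug, dose_mg_per_day=dose,
                          duration_weeks=8, outcome=Outcome.NO_RESPONSE)


first = EpisodeRecord(
    patient_id="example-003",
    onset_date=date(2019, 1, 1),
    assessment_date=date(2019, 9, 1),
    baseline_severity=SeverityAssessment(instrument=Instrument.HRSD17, score=20),
    trials=(_trial("fluoxetine", 20), _trial("sertraline", 50)),
)
apparent_relapse = EpisodeRecord(
    patient_id="example-003",
    onset_date=date(2019, 10, 1),  # one month after the previous assessment
    assessment_date=date(2020, 6, 1),
    baseline_severity=SeverityAssessment(instrument=Instrument.HRSD17, score=24),
    trials=(_trial("venlafaxine", 150),),
)

merged = merge_episodes([first, apparent_relapse])
print(f"episodes after merging: {len(merged)}")
episode = merged[0]
print(f"merged span: {episode.onset_date} → {episode.assessment_date} "
      f"({episode_duration_months(episode):.1f} months), "
      f"{len(episode.trials)} trials")
result = stage(episode)
print(f"total {result.total} ({result.band.value}): duration score "
      f"{result.dimensions.duration_score}, "
      f"{result.dimensions.n_failed_antidepressants} counted failures")
print("A ≥2-month remission gap would instead have kept two episodes, each "
      "rated on its own record.")
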