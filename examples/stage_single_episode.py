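"""Stage one depressive episode and print the MSM worksheet.

A patient with four adequately-given antidepressant failures, lithium
augmentation, an 18-month episode and a baseline HRSD17 of 22 (moderate,
non-psychotic): the treatment dimension scores 2 (level for 3-4 failures)
+ 1 (augmentation) = 3, severity 3, duration 2 — total 8, moderate band.
"""

from datetime import date

from msm_staging import (
    AugmentationRecord,
    EpisodeRecord,
    Instrument,
    Outcome,
    SeverityAssessment,
    TreatmentTrial,
    stage,
)
from msm_staging.io import _worksheet

trials = tuple(
    TreatmentTrial(
        drug_name=drug,
        dose_mg_per_day=dose,
        duration_weeks=8,
        adherent=True,
        tolerated=True,
        outcome=Outcome.NO_RESPONSE,
    )
    for drug, dose in [
        ("fluoxetine", 20), ("sertraline", 100), ("venlafaxine", 150),
        ("mirtazapine", 30),
    ]
)

episode = EpisodeRecord(
    patient_id="example-001",
    onset_date=date(2018, 12, 1),
    assessment_date=date(2020, 6, 1),  # ≈ 18 months
    baseline_severity=SeverityAssessment(
        instrument=Instrument.HRSD17, score=22, psychotic_features=False
    ),
    trials=trials,
    augmentations=(AugmentationRecord(agent_name="lithium", used=True),),
)

result = stage(episode)
print(_worksheet(result))
print(
    f"Total {result.total} sits in the {result.band.value} band (mild 3-6, "
    "moderate 7-10, severe 11-15)."
)
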