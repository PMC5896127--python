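from datetime import date

import pytest

from msm_staging import (
    EpisodeRecord,
    Instrument,
    Outcome,
    SeverityAssessment,
    TreatmentTrial,
)


def make_trial(
    drug="fluoxetine",
    dose=20.0,
    weeks=8.0,
    adherent=True,
    tolerated=True,
    outcome=Outcome.NO_RESPONSE,
    **kw,
):
    return TreatmentTrial(
        drug_name=drug,
        dose_mg_per_day=dose,
        duration_weeks=weeks,
        adherent=adherent,
        tolerated=tolerated,
        outcome=outcome,
        **kw,
    )


def make_episode(
    trials=(),
    onset=date(2019, 12, 1),
    assessment=date(2020, 6, 1),
    baseline_score=22,
    instrument=Instrument.HRSD17,
    psychotic=False,
    **kw,
):
    return EpisodeRecord(
        patient_id="p1",
        onset_date=onset,
        assessment_date=assessment,
        baseline_severity=SeverityAssessment(
            instrument=instrument, score=baseline_score, psychotic_features=psychotic
        ),
        trials=tuple(trials),
        **kw,
    )


@pytest.fixture
def failed_trial():
    return make_trial()


@pytest.fixture
def episode_one_failure():
    return make_episode(trials=[make_trial()])
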