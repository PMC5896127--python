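"""Synthetic cohorts of episode records for testing and demonstration.

No patient data ships with, or is needed by, this package: the generator
emits episode records with the same structure a treatment-history inventory
would yield — drug courses at guideline doses, augmentation and ECT
records, a baseline severity assessment on a configurable instrument mix —
spanning the full score lattice, with controllable rates of deliberately
inadequate trials (under-dosed, too short, non-adherent) to exercise the
pseudo-resistance screening.

Everything is driven by one ``numpy`` generator: a given (n, seed, profile)
always produces byte-identical records.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Optional, Sequence

import numpy as np

from .adequacy import STARTER_DOSE_TABLE
from .duration import DAYS_PER_MONTH
from .model import (
    AugmentationRecord,
    ECTCourse,
    EpisodeRecord,
    Instrument,
    Outcome,
    SeverityAssessment,
    TreatmentTrial,
)
from .severity_map import DEFAULT_THRESHOLDS, StatusCategory

#: Fixed reference assessment date; onsets are synthesized backward from it
#: so target durations are hit exactly.
ASSESSMENT_DATE = date(2020, 6, 1)

_AUGMENTING_AGENTS = ("lithium", "quetiapine", "aripiprazole", "liothyronine")

#: Representative failure count for each antidepressant level 1-5.
LEVEL_REPRESENTATIVE_FAILURES = {1: 1, 2: 3, 3: 5, 4: 7, 5: 11}

#: Representative episode duration (months) for each duration score 1-3.
SCORE_REPRESENTATIVE_MONTHS = {1: 6.0, 2: 18.0, 3: 30.0}

#: Baseline HRSD17 scores hitting each MSM severity level 1-5
#: (level 5 = severe score with psychotic features).
_HRSD_FOR_SEVERITY = {1: 10, 2: 16, 3: 22, 4: 30, 5: 30}


@dataclass(frozen=True)
class CohortProfile:
    """Distributional knobs of the synthetic cohort.

    Defaults sketch a tertiary-care treatment-resistant population: failure
    counts geometric-ish over 1-15, roughly a third augmented, ECT uncommon,
    psychotic features in one in ten, episodes a median of about a year old,
    and a modest rate of inadequate trials of each pseudo-resistance kind.
    """

    failure_count_min: int = 1
    failure_count_max: int = 15
    failure_count_geom_p: float = 0.35
    augmentation_prevalence: float = 0.30
    ect_prevalence: float = 0.10
    psychosis_rate: float = 0.10
    instruments: Sequence[Instrument] = (
        Instrument.HRSD17,
        Instrument.QIDS_C16,
        Instrument.PSR,
        Instrument.CGI,
    )
    duration_months_lognorm_mean: float = 2.5  # log-scale; median ≈ 12 months
    duration_months_lognorm_sigma: float = 0.8
    underdose_rate: float = 0.10
    short_trial_rate: float = 0.10
    nonadherence_rate: float = 0.10

    def __post_init__(self) -> None:
        if not 1 <= self.failure_count_min <= self.failure_count_max:
            raise ValueError("failure counts must satisfy 1 <= min <= max")
        for name in (
            "augmentation_prevalence", "ect_prevalence", "psychosis_rate",
            "underdose_rate", "short_trial_rate", "nonadherence_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if not 0.0 < self.failure_count_geom_p <= 1.0:
            raise ValueError("failure_count_geom_p must be in (0, 1]")

    @classmethod
    def maximal(cls) -> "CohortProfile":
        """Every record maximizes all three dimensions (total 15)."""
        return cls(
            failure_count_min=11,
            failure_count_max=15,
            augmentation_prevalence=1.0,
            ect_prevalence=1.0,
            psychosis_rate=1.0,
            instruments=(Instrument.HRSD17,),
            duration_months_lognorm_mean=3.6,  # median ≈ 37 months
            duration_months_lognorm_sigma=0.2,
            underdose_rate=0.0,
            short_trial_rate=0.0,
            nonadherence_rate=0.0,
        )


def _onset_for_months(months: float) -> date:
    return ASSESSMENT_DATE - timedelta(days=round(months * DAYS_PER_MONTH))


def _failed_trial(drug: str, duration_weeks: float = 8.0, **kw) -> TreatmentTrial:
    return TreatmentTrial(
        drug_name=drug,
        dose_mg_per_day=STARTER_DOSE_TABLE[drug],
        duration_weeks=duration_weeks,
        adherent=True,
        tolerated=True,
        outcome=Outcome.NO_RESPONSE,
        **kw,
    )


def _baseline_for_severity(
    rng: np.random.Generator, instrument: Instrument, severity: int
) -> SeverityAssessment:
    """An assessment on `instrument` whose MSM severity score is `severity`."""
    psychotic = severity == 5
    target = {
        1: StatusCategory.SUBTHRESHOLD,
        2: StatusCategory.MILD,
        3: StatusCategory.MODERATE,
        4: StatusCategory.SEVERE,
        5: StatusCategory.SEVERE,
    }[severity]
    if instrument is Instrument.ICD10_CHECKLIST:
        return SeverityAssessment(
            instrument=instrument,
            score=min(severity, 4) if psychotic else severity,
            psychotic_features=psychotic,
            assessment_date=ASSESSMENT_DATE,
        )
    for cat, lo, hi in DEFAULT_THRESHOLDS[instrument].category_intervals:
        if cat is target:
            return SeverityAssessment(
                instrument=instrument,
                score=int(rng.integers(lo, hi + 1)),
                psychotic_features=psychotic,
                assessment_date=ASSESSMENT_DATE,
            )
    raise ValueError(f"{instrument.value} has no {target.name} interval")


def generate_cohort(
    n: int, seed: int, profile: Optional[CohortProfile] = None
) -> list[EpisodeRecord]:
    """Generate ``n`` reproducible synthetic episode records.

    Same (n, seed, profile) → identical serializations. Drug names are drawn
    from the starter dose table so every trial is adjudicable with the
    default configuration.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    profile = profile or CohortProfile()
    rng = np.random.default_rng(seed)
    drugs = sorted(STARTER_DOSE_TABLE)
    records: list[EpisodeRecord] = []
    for i in range(n):
        # failure count: truncated geometric over [min, max]
        k = profile.failure_count_min + int(rng.geometric(profile.failure_count_geom_p)) - 1
        k = min(k, profile.failure_count_max)

        trials = [
            _failed_trial(drugs[int(rng.integers(len(drugs)))])
            for _ in range(k)
        ]
        # pseudo-resistance injections: deliberately inadequate extra trials
        if rng.random() < profile.underdose_rate:
            d = drugs[int(rng.integers(len(drugs)))]
            trials.append(
                TreatmentTrial(
                    drug_name=d,
                    dose_mg_per_day=STARTER_DOSE_TABLE[d] / 2,
                    duration_weeks=8.0,
                    outcome=Outcome.NO_RESPONSE,
                )
            )
        if rng.random() < profile.short_trial_rate:
            trials.append(_failed_trial(drugs[int(rng.integers(len(drugs)))], duration_weeks=3.0))
        if rng.random() < profile.nonadherence_rate:
            d = drugs[int(rng.integers(len(drugs)))]
            trials.append(
                TreatmentTrial(
                    drug_name=d,
                    dose_mg_per_day=STARTER_DOSE_TABLE[d],
                    duration_weeks=8.0,
                    adherent=False,
                    outcome=Outcome.NO_RESPONSE,
                )
            )

        augmentations = ()
        if rng.random() < profile.augmentation_prevalence:
            agent = _AUGMENTING_AGENTS[int(rng.integers(len(_AUGMENTING_AGENTS)))]
            augmentations = (
                AugmentationRecord(agent_name=agent, used=True, duration_weeks=6.0),
            )
        ect = None
        if rng.random() < profile.ect_prevalence:
            ect = ECTCourse(n_sessions=int(rng.integers(8, 13)), completed=True,
                            outcome=Outcome.NO_RESPONSE)

        psychotic = bool(rng.random() < profile.psychosis_rate)
        severity = 5 if psychotic else int(rng.integers(1, 5))
        instrument = profile.instruments[int(rng.integers(len(profile.instruments)))]
        baseline = _baseline_for_severity(rng, instrument, severity)

        months = float(
            rng.lognormal(
                profile.duration_months_lognorm_mean,
                profile.duration_months_lognorm_sigma,
            )
        )
        records.append(
            EpisodeRecord(
                patient_id=f"synth-{i:04d}",
                onset_date=_onset_for_months(months),
                assessment_date=ASSESSMENT_DATE,
                baseline_severity=baseline,
                is_first_episode=bool(rng.random() < 0.5),
                trials=tuple(trials),
                augmentations=augmentations,
                ect=ect,
            )
        )
    return records


def lattice_fixtures() -> list[EpisodeRecord]:
    """One minimal record per cell of the full score lattice.

    The lattice is antidepressant level (1-5) × augmentation (0/1) ×
    ECT (0/1) × severity (1-5) × duration (1-3): 300 records, each built to
    land exactly in its cell, for exhaustive end-to-end scoring checks.
    """
    rng = np.random.default_rng(0)  # only used to pick scores inside intervals
    records: list[EpisodeRecord] = []
    for level, n_fail in LEVEL_REPRESENTATIVE_FAILURES.items():
        for aug in (False, True):
            for ect_used in (False, True):
                for severity in range(1, 6):
                    for dur_score, months in SCORE_REPRESENTATIVE_MONTHS.items():
                        records.append(
                            EpisodeRecord(
                                patient_id=(
                                    f"lattice-L{level}-A{int(aug)}-E{int(ect_used)}"
                                    f"-S{severity}-D{dur_score}"
                                ),
                                onset_date=_onset_for_months(months),
                                assessment_date=ASSESSMENT_DATE,
                                baseline_severity=_baseline_for_severity(
                                    rng, Instrument.HRSD17, severity
                                ),
                                trials=tuple(
                                    _failed_trial("fluoxetine") for _ in range(n_fail)
                                ),
                                augmentations=(
                                    AugmentationRecord(
                                        agent_name="lithium", used=True, duration_weeks=6.0
                                    ),
                                )
                                if aug
                                else (),
                                ect=ECTCourse(
                                    n_sessions=8, completed=True, outcome=Outcome.NO_RESPONSE
                                )
                                if ect_used
                                else None,
                            )
                        )
    return records
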