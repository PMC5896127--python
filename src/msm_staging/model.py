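"""Domain types for Maudsley Staging Method (MSM) records.

The unit of rating is a single depressive episode, described the way the
Maudsley Treatment Inventory describes it: a list of antidepressant trials
(drug, dose, duration, adherence, tolerability, outcome), augmentation and
ECT records, a baseline symptom-severity assessment and the episode's onset
and assessment dates. Multi-episode patients are represented as a list of
:class:`EpisodeRecord`, one per episode.

Type/shape validation happens at construction (pydantic). Domain invariants
— score ranges, date ordering, non-negative doses — are checked by
:func:`validate_episode`, which *returns* issues instead of raising, so that
imperfect retrospective records can be loaded, inspected and reported on.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date
from typing import Optional

from pydantic import BaseModel, ConfigDict


class Outcome(str, enum.Enum):
    """End-of-trial clinical outcome of one treatment course."""

    REMITTED = "remitted"
    RESPONDED_NOT_REMITTED = "responded_not_remitted"
    NO_RESPONSE = "no_response"
    UNKNOWN = "unknown"


class Instrument(str, enum.Enum):
    """Symptom-severity rating instruments with built-in MSM threshold tables."""

    QIDS_C16 = "QIDS-C16"
    QIDS_SR16 = "QIDS-SR16"
    IDS_C = "IDS-C"
    IDS_SR = "IDS-SR"
    HRSD17 = "HRSD17"
    MADRS = "MADRS"
    CGI = "CGI"
    PSR = "PSR"
    ICD10_CHECKLIST = "ICD10-checklist"


class Verdict(str, enum.Enum):
    """Adjudication of one treatment trial for the treatment-failure dimension."""

    COUNTED_FAILURE = "counted_failure"
    REMITTED = "remitted"
    INADEQUATE = "inadequate"


class PseudoResistanceFlag(str, enum.Enum):
    """Why an apparently failed trial does not count as a true failure."""

    NON_ADHERENCE = "non_adherence"
    INTOLERANCE = "intolerance"
    INADEQUATE_DOSE = "inadequate_dose"
    INADEQUATE_DURATION = "inadequate_duration"


class Band(str, enum.Enum):
    """MSM total-score severity band."""

    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


class SeverityAssessment(BaseModel):
    """One instrument total score with a psychotic-features flag.

    ``score`` is the instrument *total* (item-level scoring is out of scope);
    for the ICD10 checklist it is the ordinal severity category 1-5 directly.
    """

    model_config = ConfigDict(frozen=True)

    instrument: Instrument
    score: int
    psychotic_features: bool = False
    assessment_date: Optional[date] = None


class TreatmentTrial(BaseModel):
    """One antidepressant course.

    Duration may be given explicitly in weeks, as start/end dates, or both;
    when both are present the dates are authoritative and a disagreement of
    more than one week is flagged by :func:`validate_episode` (retrospective
    treatment histories are often date-imprecise).

    ``confirmatory_outcome`` is a second remission-status measure taken after
    the end-of-trial one; it is only consulted under the sustained
    (two-months-in-remission) remission rule.
    """

    model_config = ConfigDict(frozen=True)

    drug_name: str
    dose_mg_per_day: float
    duration_weeks: Optional[float] = None
    start_date: Optional[date] = None
    end_date: Optional[date] = None
    adherent: bool = True
    tolerated: bool = True
    outcome: Outcome = Outcome.UNKNOWN
    instrument_outcome: Optional[SeverityAssessment] = None
    confirmatory_outcome: Optional[SeverityAssessment] = None

    @property
    def effective_duration_weeks(self) -> Optional[float]:
        """Trial duration in weeks; dates take precedence over duration_weeks."""
        if self.start_date is not None and self.end_date is not None:
            return (self.end_date - self.start_date).days / 7.0
        return self.duration_weeks


class AugmentationRecord(BaseModel):
    """Use of a non-antidepressant augmenting agent (e.g. lithium)."""

    model_config = ConfigDict(frozen=True)

    agent_name: str
    used: bool = True
    duration_weeks: float = 0.0


class ECTCourse(BaseModel):
    """A course of electroconvulsive therapy."""

    model_config = ConfigDict(frozen=True)

    n_sessions: int
    completed: bool = True
    outcome: Outcome = Outcome.UNKNOWN


class EpisodeRecord(BaseModel):
    """One depressive episode: the MSM's unit of staging.

    ``onset_date`` is the onset of the full episode for first episodes and
    the onset of prodromal relapse symptoms for subsequent episodes.
    """

    model_config = ConfigDict(frozen=True)

    patient_id: str
    onset_date: date
    assessment_date: date
    baseline_severity: SeverityAssessment
    is_first_episode: bool = True
    trials: tuple[TreatmentTrial, ...] = ()
    augmentations: tuple[AugmentationRecord, ...] = ()
    ect: Optional[ECTCourse] = None


class DimensionScores(BaseModel):
    """The three MSM dimension sub-scores plus the treatment-dimension parts."""

    model_config = ConfigDict(frozen=True)

    treatment_failure_score: int  # 1-7 = antidepressant level + aug + ECT
    severity_score: int  # 1-5
    duration_score: int  # 1-3
    n_failed_antidepressants: int
    augmentation_used: bool
    ect_used: bool


class TrialAdjudication(BaseModel):
    """Verdict for one trial, with the index into the episode's trial list."""

    model_config = ConfigDict(frozen=True)

    trial_index: int
    verdict: Verdict
    reason: str


class MSMResult(BaseModel):
    """A staged episode: total 3-15, band, sub-scores and the adjudication trail."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    total: int
    band: Band
    dimensions: DimensionScores
    pseudo_resistance_flags: tuple[PseudoResistanceFlag, ...] = ()
    trial_adjudications: tuple[TrialAdjudication, ...] = ()


class NotTreatmentResistant(BaseModel):
    """Explicit non-score result: no counted antidepressant failure.

    The MSM scale starts at the first adequate treatment failure, so an
    episode with zero counted failures is not treatment-resistant rather
    than scoring zero.
    """

    model_config = ConfigDict(frozen=True)

    patient_id: str
    status: str = "not_treatment_resistant"
    pseudo_resistance_flags: tuple[PseudoResistanceFlag, ...] = ()
    trial_adjudications: tuple[TrialAdjudication, ...] = ()


@dataclass(frozen=True)
class ValidationIssue:
    """One domain-invariant violation, with a dotted field path."""

    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.message}"


class StagingRefusedError(ValueError):
    """The record cannot be staged (e.g. baseline already in remission)."""


class NotTreatmentResistantError(ValueError):
    """Fewer than one counted antidepressant failure: MSM does not apply."""


# Admissible total-score ranges per instrument; ICD10 checklist scores are the
# ordinal severity categories themselves.
INSTRUMENT_RANGES: dict[Instrument, tuple[int, int]] = {
    Instrument.QIDS_C16: (0, 27),
    Instrument.QIDS_SR16: (0, 27),
    Instrument.IDS_C: (0, 84),
    Instrument.IDS_SR: (0, 84),
    Instrument.HRSD17: (0, 52),
    Instrument.MADRS: (0, 60),
    Instrument.CGI: (1, 7),
    Instrument.PSR: (1, 7),
    Instrument.ICD10_CHECKLIST: (1, 5),
}


def _check_assessment(a: SeverityAssessment, path: str, issues: list[ValidationIssue]) -> None:
    lo, hi = INSTRUMENT_RANGES[a.instrument]
    if not lo <= a.score <= hi:
        issues.append(
            ValidationIssue(
                f"{path}.score",
                f"{a.instrument.value} score {a.score} outside admissible range [{lo}, {hi}]",
            )
        )


def validate_episode(record: EpisodeRecord) -> list[ValidationIssue]:
    """Check every domain invariant of an episode record.

    Returns an empty list iff the record is well formed. Issues carry the
    dotted path of the offending field; nothing is raised.
    """
    issues: list[ValidationIssue] = []

    if record.assessment_date < record.onset_date:
        issues.append(
            ValidationIssue(
                "assessment_date",
                f"assessment_date {record.assessment_date} precedes onset_date {record.onset_date}",
            )
        )
    if not record.patient_id:
        issues.append(ValidationIssue("patient_id", "patient_id must be non-empty"))

    _check_assessment(record.baseline_severity, "baseline_severity", issues)

    for i, t in enumerate(record.trials):
        path = f"trials[{i}]"
        if not t.drug_name:
            issues.append(ValidationIssue(f"{path}.drug_name", "drug_name must be non-empty"))
        if t.dose_mg_per_day < 0:
            issues.append(
                ValidationIssue(f"{path}.dose_mg_per_day", "dose must be non-negative")
            )
        if t.duration_weeks is not None and t.duration_weeks < 0:
            issues.append(
                ValidationIssue(f"{path}.duration_weeks", "duration must be non-negative")
            )
        if (t.start_date is None) != (t.end_date is None):
            issues.append(
                ValidationIssue(path, "start_date and end_date must be given together")
            )
        if t.start_date is not None and t.end_date is not None:
            if t.end_date < t.start_date:
                issues.append(ValidationIssue(f"{path}.end_date", "end_date precedes start_date"))
            elif t.duration_weeks is not None:
                derived = (t.end_date - t.start_date).days / 7.0
                if abs(derived - t.duration_weeks) > 1.0:
                    issues.append(
                        ValidationIssue(
                            f"{path}.duration_weeks",
                            f"duration_weeks {t.duration_weeks} disagrees with dates "
                            f"({derived:.1f} weeks) by more than one week",
                        )
                    )
        if t.duration_weeks is None and t.start_date is None:
            issues.append(
                ValidationIssue(path, "either duration_weeks or start/end dates required")
            )
        if t.instrument_outcome is not None:
            _check_assessment(t.instrument_outcome, f"{path}.instrument_outcome", issues)
        if t.confirmatory_outcome is not None:
            _check_assessment(t.confirmatory_outcome, f"{path}.confirmatory_outcome", issues)

    for i, a in enumerate(record.augmentations):
        if a.duration_weeks < 0:
            issues.append(
                ValidationIssue(
                    f"augmentations[{i}].duration_weeks", "duration must be non-negative"
                )
            )
        if not a.agent_name:
            issues.append(
                ValidationIssue(f"augmentations[{i}].agent_name", "agent_name must be non-empty")
            )

    if record.ect is not None and record.ect.n_sessions < 0:
        issues.append(ValidationIssue("ect.n_sessions", "n_sessions must be non-negative"))

    return issues
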