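"""The MSM scoring pipeline: three dimensions → total 3-15 → severity band.

Dimension 1 (treatment failure, 1-7) is an antidepressant-failure level
(1-5) plus binary indicators for augmentation and a qualifying ECT course.
Dimension 2 (symptom severity at baseline, 1-5) and dimension 3 (episode
duration, 1-3) come from the severity and duration modules. The total is
their plain sum; bands are mild 3-6, moderate 7-10, severe 11-15.

Treatment-resistance starts at the first adequate antidepressant failure:
an episode with zero counted failures gets an explicit not-treatment-
resistant status, never a score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

from .adequacy import (
    AdequacyConfig,
    adjudicate_episode,
    augmentation_used,
    count_failed_antidepressants,
    ect_counts,
    pseudo_resistance_flags,
)
from .duration import DurationConfig, duration_category, episode_duration_months
from .model import (
    Band,
    DimensionScores,
    EpisodeRecord,
    MSMResult,
    NotTreatmentResistant,
    NotTreatmentResistantError,
    Verdict,
    validate_episode,
)
from .severity_map import ThresholdTable, msm_severity_score


@dataclass(frozen=True)
class StagingConfig:
    """Bundle of per-dimension configuration used by :func:`stage`."""

    adequacy: AdequacyConfig = field(default_factory=AdequacyConfig)
    duration: DurationConfig = field(default_factory=DurationConfig)
    thresholds: Optional[ThresholdTable] = None  # None → built-in tables


def antidepressant_level(n_failures: int) -> int:
    """Failure-count level 1-5: 1-2→1, 3-4→2, 5-6→3, 7-10→4, >10→5."""
    if n_failures < 1:
        raise NotTreatmentResistantError(
            "fewer than one counted antidepressant failure: not treatment-resistant"
        )
    if n_failures <= 2:
        return 1
    if n_failures <= 4:
        return 2
    if n_failures <= 6:
        return 3
    if n_failures <= 10:
        return 4
    return 5


def treatment_dimension_score(
    n_failures: int, augmentation_used: bool, ect_used: bool
) -> int:
    """Dimension 1 (1-7): antidepressant level + augmentation + ECT indicators."""
    return antidepressant_level(n_failures) + int(augmentation_used) + int(ect_used)


def total_score(dimensions: DimensionScores) -> int:
    """Sum of the three dimension scores; always in [3, 15]."""
    d = dimensions
    if not 1 <= d.treatment_failure_score <= 7:
        raise ValueError(f"treatment_failure_score {d.treatment_failure_score} outside [1, 7]")
    if not 1 <= d.severity_score <= 5:
        raise ValueError(f"severity_score {d.severity_score} outside [1, 5]")
    if not 1 <= d.duration_score <= 3:
        raise ValueError(f"duration_score {d.duration_score} outside [1, 3]")
    return d.treatment_failure_score + d.severity_score + d.duration_score


def band(total: int) -> Band:
    """Severity band of a total: 3-6 mild, 7-10 moderate, 11-15 severe."""
    if not 3 <= total <= 15:
        raise ValueError(f"total {total} outside the MSM range [3, 15]")
    if total <= 6:
        return Band.MILD
    if total <= 10:
        return Band.MODERATE
    return Band.SEVERE


def stage(
    record: EpisodeRecord, config: Optional[StagingConfig] = None
) -> Union[MSMResult, NotTreatmentResistant]:
    """Stage one episode end to end.

    Adjudicates every trial, counts failures, scores the three dimensions
    and assembles the total, band, pseudo-resistance flags and the
    adjudication trail. Returns :class:`NotTreatmentResistant` when no trial
    is a counted failure; raises :class:`StagingRefusedError` when the
    baseline assessment indicates remission and :class:`ValueError` when the
    record fails validation.
    """
    config = config or StagingConfig()
    issues = validate_episode(record)
    if issues:
        raise ValueError(
            "record fails validation: " + "; ".join(str(i) for i in issues)
        )

    adjudications = adjudicate_episode(record, config.adequacy, config.thresholds)
    flags = pseudo_resistance_flags(record, config.adequacy)
    n_failures = sum(1 for a in adjudications if a.verdict is Verdict.COUNTED_FAILURE)
    if n_failures < 1:
        return NotTreatmentResistant(
            patient_id=record.patient_id,
            pseudo_resistance_flags=tuple(flags),
            trial_adjudications=tuple(adjudications),
        )

    severity = msm_severity_score(record.baseline_severity, config.thresholds)
    months = episode_duration_months(record, config.duration)
    _, dur_score = duration_category(
        months, table5_convention=config.duration.table5_convention
    )
    aug = augmentation_used(record)
    ect = ect_counts(record.ect, config.adequacy)

    dims = DimensionScores(
        treatment_failure_score=treatment_dimension_score(n_failures, aug, ect),
        severity_score=severity,
        duration_score=dur_score,
        n_failed_antidepressants=n_failures,
        augmentation_used=aug,
        ect_used=ect,
    )
    total = total_score(dims)
    return MSMResult(
        patient_id=record.patient_id,
        total=total,
        band=band(total),
        dimensions=dims,
        pseudo_resistance_flags=tuple(flags),
        trial_adjudications=tuple(adjudications),
    )
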