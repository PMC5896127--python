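"""Trial-adequacy adjudication: adequate failure, remission, or pseudo-resistance.

An antidepressant course only counts toward treatment-resistance if it was an
*adequate* trial: given at or above the drug's minimum effective daily dose,
for at least six weeks (four in research mode), with adherence and without
being stopped for intolerance. Failure means failure to reach clinical
remission — a response short of remission still counts as a failure.
Inadequate trials are excluded from the failure tally and surface as
pseudo-resistance flags instead.

Minimum effective doses are configuration, not clinical fact baked into
code: a starter table covering common UK-prescribed antidepressants ships
with the package, and unknown drugs fail loudly rather than pass silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import yaml

from .model import (
    ECTCourse,
    EpisodeRecord,
    Outcome,
    PseudoResistanceFlag,
    TreatmentTrial,
    TrialAdjudication,
    Verdict,
)
from .severity_map import ThresholdTable, is_remission

logger = logging.getLogger(__name__)

#: Starter minimum effective daily doses (mg/day), compiled from standard
#: prescribing-guideline conventions; override per site via YAML/CSV.
STARTER_DOSE_TABLE: dict[str, float] = {
    "agomelatine": 25,
    "amitriptyline": 75,
    "bupropion": 150,
    "citalopram": 20,
    "clomipramine": 75,
    "duloxetine": 60,
    "escitalopram": 10,
    "fluoxetine": 20,
    "fluvoxamine": 100,
    "imipramine": 75,
    "lofepramine": 140,
    "mirtazapine": 30,
    "moclobemide": 300,
    "nortriptyline": 75,
    "paroxetine": 20,
    "phenelzine": 45,
    "reboxetine": 8,
    "sertraline": 50,
    "tranylcypromine": 20,
    "trazodone": 150,
    "venlafaxine": 75,
    "vortioxetine": 10,
}


class UnknownDrugError(KeyError):
    """Drug missing from the dose table: supply a dose-table entry."""


@dataclass(frozen=True)
class AdequacyConfig:
    """Gates a trial must pass to count as an adequate treatment exposure.

    ``research_mode_four_weeks`` lowers the minimum duration from six weeks
    to four, the early-detection research convention.
    ``remission_duration_rule='sustained_two_months'`` additionally requires
    a confirmatory remission measure at least 60 days after the end-of-trial
    one; with a single measure it degrades to the single-measure rule with a
    logged warning.
    """

    research_mode_four_weeks: bool = False
    dose_table: Mapping[str, float] = field(default_factory=lambda: dict(STARTER_DOSE_TABLE))
    ect_min_sessions: int = 8
    remission_duration_rule: str = "single_measure"  # or "sustained_two_months"

    def __post_init__(self) -> None:
        if self.remission_duration_rule not in ("single_measure", "sustained_two_months"):
            raise ValueError(f"unknown remission rule {self.remission_duration_rule!r}")
        bad = [d for d, v in self.dose_table.items() if v <= 0]
        if bad:
            raise ValueError(f"dose-table entries must be positive: {bad}")

    @property
    def min_duration_weeks(self) -> float:
        return 4.0 if self.research_mode_four_weeks else 6.0


def load_dose_table(path: Union[str, Path]) -> dict[str, float]:
    """Load a dose table from YAML ({drug: mg}) or CSV (drug_name, min_effective_dose_mg)."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of drug_name -> mg/day")
        return {str(k).lower(): float(v) for k, v in data.items()}
    import csv

    with open(path, newline="") as fh:
        return {
            row["drug_name"].lower(): float(row["min_effective_dose_mg"])
            for row in csv.DictReader(fh)
        }


def is_adequate_trial(
    trial: TreatmentTrial, config: Optional[AdequacyConfig] = None
) -> tuple[bool, list[PseudoResistanceFlag]]:
    """Adequacy of one trial; reasons enumerate *every* failed gate."""
    config = config or AdequacyConfig()
    drug = trial.drug_name.lower()
    if drug not in config.dose_table:
        raise UnknownDrugError(
            f"unknown drug {trial.drug_name!r}: supply a dose-table entry"
        )
    reasons: list[PseudoResistanceFlag] = []
    if trial.dose_mg_per_day < config.dose_table[drug]:
        reasons.append(PseudoResistanceFlag.INADEQUATE_DOSE)
    duration = trial.effective_duration_weeks
    if duration is None or duration < config.min_duration_weeks:
        reasons.append(PseudoResistanceFlag.INADEQUATE_DURATION)
    if not trial.adherent:
        reasons.append(PseudoResistanceFlag.NON_ADHERENCE)
    if not trial.tolerated:
        reasons.append(PseudoResistanceFlag.INTOLERANCE)
    return (not reasons, reasons)


def _reached_remission(
    trial: TreatmentTrial,
    config: AdequacyConfig,
    thresholds: Optional[ThresholdTable],
) -> Optional[bool]:
    """True/False if the trial outcome is ratable, None if unratable."""
    single: Optional[bool] = None
    if trial.outcome is Outcome.REMITTED:
        single = True
    elif trial.outcome in (Outcome.RESPONDED_NOT_REMITTED, Outcome.NO_RESPONSE):
        single = False
    if trial.instrument_outcome is not None:
        single = is_remission(
            trial.instrument_outcome.instrument, trial.instrument_outcome.score, thresholds
        )
    if single is None:
        return None
    if config.remission_duration_rule == "single_measure" or not single:
        return single
    # sustained rule: need a confirmatory remission measure >= 60 days later
    first, second = trial.instrument_outcome, trial.confirmatory_outcome
    if (
        first is None
        or second is None
        or first.assessment_date is None
        or second.assessment_date is None
    ):
        logger.warning(
            "sustained_two_months remission rule requested for %s but only one "
            "dated remission measure available; falling back to single_measure",
            trial.drug_name,
        )
        return single
    gap_days = (second.assessment_date - first.assessment_date).days
    if gap_days < 60:
        logger.warning(
            "confirmatory measure for %s only %d days after the first (<60); "
            "falling back to single_measure", trial.drug_name, gap_days,
        )
        return single
    return is_remission(second.instrument, second.score, thresholds)


def adjudicate_trial(
    trial: TreatmentTrial,
    config: Optional[AdequacyConfig] = None,
    thresholds: Optional[ThresholdTable] = None,
) -> tuple[Verdict, str]:
    """One verdict per trial: counted_failure, remitted, or inadequate.

    A recorded end-of-trial instrument score takes precedence over the
    categorical outcome; an adequate trial whose outcome is unknown and
    unscored is adjudicated inadequate (unratable) rather than silently
    counted as a failure.
    """
    config = config or AdequacyConfig()
    adequate, reasons = is_adequate_trial(trial, config)
    if not adequate:
        return (
            Verdict.INADEQUATE,
            "inadequate: " + ", ".join(r.value for r in reasons),
        )
    remitted = _reached_remission(trial, config, thresholds)
    if remitted is None:
        return (Verdict.INADEQUATE, "inadequate (unratable): outcome unknown and no instrument score")
    if remitted:
        return (Verdict.REMITTED, "reached clinical remission")
    return (Verdict.COUNTED_FAILURE, "adequate trial without remission")


def adjudicate_episode(
    record: EpisodeRecord,
    config: Optional[AdequacyConfig] = None,
    thresholds: Optional[ThresholdTable] = None,
) -> list[TrialAdjudication]:
    """Adjudicate every trial in an episode; verdicts partition the trial list."""
    config = config or AdequacyConfig()
    return [
        TrialAdjudication(trial_index=i, verdict=v, reason=reason)
        for i, t in enumerate(record.trials)
        for v, reason in [adjudicate_trial(t, config, thresholds)]
    ]


def count_failed_antidepressants(
    record: EpisodeRecord,
    config: Optional[AdequacyConfig] = None,
    thresholds: Optional[ThresholdTable] = None,
) -> int:
    """Number of counted failures; distinct courses of one drug count separately."""
    return sum(
        1
        for a in adjudicate_episode(record, config, thresholds)
        if a.verdict is Verdict.COUNTED_FAILURE
    )


def pseudo_resistance_flags(
    record: EpisodeRecord,
    config: Optional[AdequacyConfig] = None,
) -> list[PseudoResistanceFlag]:
    """Union (first-seen order) of adequacy-gate failures across all trials."""
    config = config or AdequacyConfig()
    seen: list[PseudoResistanceFlag] = []
    for t in record.trials:
        _, reasons = is_adequate_trial(t, config)
        for r in reasons:
            if r not in seen:
                seen.append(r)
    return seen


def ect_counts(
    ect: Optional[ECTCourse], config: Optional[AdequacyConfig] = None
) -> bool:
    """Whether an ECT course scores the ECT indicator (≥8 sessions by default).

    Delivery of a qualifying course counts regardless of its outcome; the
    indicator records exposure, not failure.
    """
    if ect is None:
        return False
    config = config or AdequacyConfig()
    return ect.n_sessions >= config.ect_min_sessions


def augmentation_used(record: EpisodeRecord) -> bool:
    """Whether any augmentation agent was used (binary indicator; any documented use)."""
    return any(a.used for a in record.augmentations)
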