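"""Episode dating, merging across short remissions, and the duration dimension.

The duration dimension rates the length of the *presenting* episode,
including any period before treatment began. Apparent episodes separated by
less than two months of remission are treated as a continuation of one
illness process and merged; gaps of two months or more keep episodes
distinct (each then gets its own rating).

Two printed boundary conventions exist for the category cut-offs: the scored
convention (acute ≤12 months, sub-acute 13-24, chronic >24 → intervals
(-inf,12], (12,24], (24,inf)) is the default; a toggle flips to the
interview-sheet convention ([0,12), [12,24), [24,inf)). They differ only at
exactly 12 or 24 months.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .model import EpisodeRecord

DAYS_PER_MONTH = 30.44  # mean Gregorian month


@dataclass(frozen=True)
class DurationConfig:
    """Episode-separation and month-length conventions."""

    separation_months: float = 2.0
    month_length_days: float = DAYS_PER_MONTH
    table5_convention: bool = False  # half-open [0,12), [12,24) category bounds

    def __post_init__(self) -> None:
        if self.separation_months <= 0:
            raise ValueError("separation_months must be positive")


def episode_duration_months(
    record: EpisodeRecord, config: Optional[DurationConfig] = None
) -> float:
    """Duration of the presenting episode in (mean) months, onset → assessment."""
    config = config or DurationConfig()
    if record.assessment_date < record.onset_date:
        raise ValueError("assessment_date precedes onset_date")
    return (record.assessment_date - record.onset_date).days / config.month_length_days


def duration_category(
    months: float, *, table5_convention: bool = False
) -> tuple[str, int]:
    """Duration category and its MSM score: acute 1, subacute 2, chronic 3."""
    if months < 0:
        raise ValueError("duration must be non-negative")
    if table5_convention:
        if months < 12:
            return ("acute", 1)
        if months < 24:
            return ("subacute", 2)
        return ("chronic", 3)
    if months <= 12:
        return ("acute", 1)
    if months <= 24:
        return ("subacute", 2)
    return ("chronic", 3)


def merge_episodes(
    episodes: Sequence[EpisodeRecord], config: Optional[DurationConfig] = None
) -> list[EpisodeRecord]:
    """Merge consecutive episodes separated by sub-threshold remission gaps.

    Episodes must be one patient's, sorted by onset. A gap (next onset minus
    previous assessment) shorter than ``separation_months`` merges the pair:
    onset of the first, assessment of the last, trials and augmentations
    concatenated so failures from the continuation period count toward the
    single episode. When both halves carry an ECT course the larger course is
    kept (only the binary indicator is scored). Idempotent.
    """
    config = config or DurationConfig()
    if not episodes:
        return []
    threshold_days = config.separation_months * config.month_length_days
    merged = [episodes[0]]
    for nxt in episodes[1:]:
        prev = merged[-1]
        if nxt.onset_date < prev.onset_date:
            raise ValueError("episodes must be sorted by onset_date")
        gap_days = (nxt.onset_date - prev.assessment_date).days
        if gap_days < 0:
            raise ValueError(
                f"overlapping episodes: onset {nxt.onset_date} precedes "
                f"previous assessment {prev.assessment_date}"
            )
        if gap_days < threshold_days:
            ect = prev.ect
            if nxt.ect is not None and (ect is None or nxt.ect.n_sessions > ect.n_sessions):
                ect = nxt.ect
            merged[-1] = prev.model_copy(
                update={
                    "assessment_date": nxt.assessment_date,
                    "trials": prev.trials + nxt.trials,
                    "augmentations": prev.augmentations + nxt.augmentations,
                    "ect": ect,
                }
            )
        else:
            merged.append(nxt)
    return merged
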