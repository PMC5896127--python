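"""Instrument-score → clinical-status → MSM severity-dimension mapping.

Every supported instrument total maps onto a six-level clinical-status scale
(remission < subthreshold < mild < moderate < severe < very_severe); the MSM
severity dimension (1-5) is then read off that status, with psychotic
features overriding to the maximum of 5 — the top MSM severity level is
defined by psychosis, not scale magnitude.

The threshold tables are data, not code: the built-ins below can be exported
to, or replaced from, a CSV of (instrument, category, lo, hi) rows. For
QIDS/IDS/HRSD the published rows give five intervals against six status
categories; the built-ins assign them to remission…severe and leave
very_severe unpopulated (both map to MSM severity 4, so staging is
unaffected; a custom table may split the top interval). The published MADRS
row is ambiguous about column alignment and MADRS is therefore disabled
until an explicit table is supplied.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

from .model import INSTRUMENT_RANGES, Instrument, SeverityAssessment, StagingRefusedError


class StatusCategory(enum.IntEnum):
    """Ordered clinical-status categories (ascending severity)."""

    REMISSION = 0
    SUBTHRESHOLD = 1
    MILD = 2
    MODERATE = 3
    SEVERE = 4
    VERY_SEVERE = 5

    @property
    def label(self) -> str:
        return self.name.lower()


@dataclass(frozen=True)
class InstrumentThresholds:
    """Contiguous, non-overlapping integer intervals tiling an instrument's range."""

    instrument: Instrument
    # ordered (category, lo, hi) with inclusive bounds
    category_intervals: tuple[tuple[StatusCategory, int, int], ...]

    def __post_init__(self) -> None:
        lo, hi = INSTRUMENT_RANGES[self.instrument]
        intervals = self.category_intervals
        if not intervals:
            raise ValueError(f"{self.instrument.value}: empty threshold table")
        if intervals[0][1] != lo or intervals[-1][2] != hi:
            raise ValueError(
                f"{self.instrument.value}: intervals must cover the full range [{lo}, {hi}]"
            )
        for (c1, _, h1), (c2, l2, _) in zip(intervals, intervals[1:]):
            if l2 != h1 + 1:
                raise ValueError(f"{self.instrument.value}: gap/overlap at {h1}/{l2}")
            if c2 <= c1:
                raise ValueError(f"{self.instrument.value}: categories must be increasing")

    def category_of(self, score: int) -> StatusCategory:
        for cat, lo, hi in self.category_intervals:
            if lo <= score <= hi:
                return cat
        lo, hi = INSTRUMENT_RANGES[self.instrument]
        raise ValueError(
            f"score {score} out of range [{lo}, {hi}] for {self.instrument.value}"
        )


def _t(instrument: Instrument, *rows: tuple[StatusCategory, int, int]) -> InstrumentThresholds:
    return InstrumentThresholds(instrument, tuple(rows))


_C = StatusCategory

#: Built-in threshold tables (version 1). QIDS/IDS/HRSD rows carry five
#: intervals (no very_severe); CGI and PSR carry all six. MADRS is absent:
#: supply a custom table to enable it. ICD10-checklist scores are ordinal
#: severity categories and bypass interval lookup entirely.
DEFAULT_THRESHOLDS: dict[Instrument, InstrumentThresholds] = {
    Instrument.QIDS_C16: _t(
        Instrument.QIDS_C16,
        (_C.REMISSION, 0, 5), (_C.SUBTHRESHOLD, 6, 10), (_C.MILD, 11, 15),
        (_C.MODERATE, 16, 20), (_C.SEVERE, 21, 27),
    ),
    Instrument.QIDS_SR16: _t(
        Instrument.QIDS_SR16,
        (_C.REMISSION, 0, 5), (_C.SUBTHRESHOLD, 6, 10), (_C.MILD, 11, 15),
        (_C.MODERATE, 16, 20), (_C.SEVERE, 21, 27),
    ),
    Instrument.IDS_C: _t(
        Instrument.IDS_C,
        (_C.REMISSION, 0, 11), (_C.SUBTHRESHOLD, 12, 23), (_C.MILD, 24, 36),
        (_C.MODERATE, 37, 46), (_C.SEVERE, 47, 84),
    ),
    Instrument.IDS_SR: _t(
        Instrument.IDS_SR,
        (_C.REMISSION, 0, 13), (_C.SUBTHRESHOLD, 14, 25), (_C.MILD, 26, 38),
        (_C.MODERATE, 39, 48), (_C.SEVERE, 49, 84),
    ),
    Instrument.HRSD17: _t(
        Instrument.HRSD17,
        (_C.REMISSION, 0, 7), (_C.SUBTHRESHOLD, 8, 13), (_C.MILD, 14, 19),
        (_C.MODERATE, 20, 25), (_C.SEVERE, 26, 52),
    ),
    Instrument.CGI: _t(
        Instrument.CGI,
        (_C.REMISSION, 1, 1), (_C.SUBTHRESHOLD, 2, 2), (_C.MILD, 3, 3),
        (_C.MODERATE, 4, 4), (_C.SEVERE, 5, 6), (_C.VERY_SEVERE, 7, 7),
    ),
    Instrument.PSR: _t(
        Instrument.PSR,
        (_C.REMISSION, 1, 2), (_C.SUBTHRESHOLD, 3, 3), (_C.MILD, 4, 4),
        (_C.MODERATE, 5, 5), (_C.SEVERE, 6, 6), (_C.VERY_SEVERE, 7, 7),
    ),
}

THRESHOLD_TABLE_VERSION = "builtin-1"

# Ordinal ICD10 checklist categories → status, for status queries; the MSM
# severity score uses the ordinal directly.
_ICD10_STATUS = {
    1: _C.SUBTHRESHOLD,
    2: _C.MILD,
    3: _C.MODERATE,
    4: _C.SEVERE,
    5: _C.VERY_SEVERE,
}

#: Clinical status → MSM severity-dimension score. very_severe shares 4 with
#: severe: level 5 is reserved for psychotic depression.
_STATUS_TO_MSM = {
    _C.SUBTHRESHOLD: 1,
    _C.MILD: 2,
    _C.MODERATE: 3,
    _C.SEVERE: 4,
    _C.VERY_SEVERE: 4,
}

ThresholdTable = Mapping[Instrument, InstrumentThresholds]


def _require_int(score: object) -> int:
    # reject floats rather than round: 7.5 on the HRSD is a data error
    if isinstance(score, bool) or not isinstance(score, int):
        raise TypeError(f"instrument scores must be integers, got {score!r}")
    return score


def status_of(
    instrument: Union[Instrument, str],
    score: int,
    thresholds: Optional[ThresholdTable] = None,
) -> StatusCategory:
    """Clinical-status category for an instrument total score."""
    instrument = Instrument(instrument)
    score = _require_int(score)
    if instrument is Instrument.ICD10_CHECKLIST:
        if score not in _ICD10_STATUS:
            raise ValueError(f"score {score} out of range [1, 5] for ICD10-checklist")
        return _ICD10_STATUS[score]
    table = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    if instrument not in table:
        raise ValueError(
            f"no threshold table for {instrument.value}; supply one explicitly"
            + (" (the published MADRS mapping is ambiguous)"
               if instrument is Instrument.MADRS else "")
        )
    return table[instrument].category_of(score)


def is_remission(
    instrument: Union[Instrument, str],
    score: int,
    thresholds: Optional[ThresholdTable] = None,
) -> bool:
    """True iff the score sits in the instrument's remission interval."""
    return status_of(instrument, score, thresholds) is StatusCategory.REMISSION


def msm_severity_score(
    assessment: SeverityAssessment,
    thresholds: Optional[ThresholdTable] = None,
) -> int:
    """MSM severity-dimension score (1-5) for a baseline assessment.

    Psychotic features force the maximum score of 5 regardless of the
    instrument total. A remission-status assessment is refused: there is no
    current syndromal or subsyndromal episode to stage.
    """
    if assessment.instrument is Instrument.ICD10_CHECKLIST:
        score = _require_int(assessment.score)
        if score not in _ICD10_STATUS:
            raise ValueError(f"score {score} out of range [1, 5] for ICD10-checklist")
        return 5 if assessment.psychotic_features else score
    status = status_of(assessment.instrument, assessment.score, thresholds)
    if status is StatusCategory.REMISSION:
        raise StagingRefusedError(
            "baseline assessment indicates remission: "
            "no current syndromal/subsyndromal episode to stage"
        )
    if assessment.psychotic_features:
        return 5
    return _STATUS_TO_MSM[status]


def export_thresholds_csv(path: Union[str, Path], thresholds: Optional[ThresholdTable] = None) -> None:
    """Write a threshold table as CSV rows (instrument, category, lo, hi)."""
    table = DEFAULT_THRESHOLDS if thresholds is None else thresholds
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["instrument", "category", "lo", "hi"])
        for inst in table:
            for cat, lo, hi in table[inst].category_intervals:
                writer.writerow([inst.value, cat.label, lo, hi])


def import_thresholds_csv(path: Union[str, Path]) -> dict[Instrument, InstrumentThresholds]:
    """Read a threshold table from CSV; intervals are validated on load."""
    rows: dict[Instrument, list[tuple[StatusCategory, int, int]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            inst = Instrument(row["instrument"])
            cat = StatusCategory[row["category"].upper()]
            rows.setdefault(inst, []).append((cat, int(row["lo"]), int(row["hi"])))
    return {
        inst: InstrumentThresholds(inst, tuple(sorted(iv, key=lambda r: r[1])))
        for inst, iv in rows.items()
    }


def iter_all_scores(instrument: Instrument) -> Iterable[int]:
    """All admissible integer scores for an instrument (for exhaustive checks)."""
    lo, hi = INSTRUMENT_RANGES[instrument]
    return range(lo, hi + 1)
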