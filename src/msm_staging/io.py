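"""Reading episode records and writing staging reports.

Two input formats are supported:

* **JSON** — one document containing a list of episode objects (schema in
  ``docs/episode_schema.json``).
* **CSV** — an episode-header file (one row per episode) plus a trials
  sidecar (one row per trial, keyed by ``patient_id``); by default the
  sidecar is found by replacing the header file's ``.csv`` suffix with
  ``.trials.csv``.

Reports are written as JSON, CSV, or a clinician-readable text worksheet;
the JSON and CSV reports carry identical fields.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .model import (
    AugmentationRecord,
    ECTCourse,
    EpisodeRecord,
    MSMResult,
    NotTreatmentResistant,
    SeverityAssessment,
    TreatmentTrial,
    ValidationIssue,
    validate_episode,
)

logger = logging.getLogger(__name__)

Result = Union[MSMResult, NotTreatmentResistant]


class EpisodeLoadError(ValueError):
    """Raised in strict mode when any record fails to parse or validate."""

    def __init__(self, issues: Sequence[ValidationIssue]):
        self.issues = list(issues)
        super().__init__(
            "invalid episode records: " + "; ".join(str(i) for i in issues)
        )


def _trials_sidecar(path: Path) -> Path:
    return path.with_suffix(".trials.csv")


def read_episodes(
    path: Union[str, Path],
    format: str = "json",
    *,
    strict: bool = False,
    trials_path: Optional[Union[str, Path]] = None,
) -> list[EpisodeRecord]:
    """Read and validate episode records from a JSON or CSV file.

    Invalid records are skipped with a logged warning carrying row/field
    provenance; with ``strict=True`` any issue is fatal
    (:class:`EpisodeLoadError`).
    """
    records, issues = read_episodes_with_issues(
        path, format, trials_path=trials_path
    )
    if issues:
        if strict:
            raise EpisodeLoadError(issues)
        for issue in issues:
            logger.warning("skipping invalid record: %s", issue)
    return records


def read_episodes_with_issues(
    path: Union[str, Path],
    format: str = "json",
    *,
    trials_path: Optional[Union[str, Path]] = None,
) -> tuple[list[EpisodeRecord], list[ValidationIssue]]:
    """As :func:`read_episodes`, returning (valid records, issues) explicitly."""
    path = Path(path)
    if format == "json":
        raw = path.read_text()
        if not raw.strip():
            logger.warning("%s is empty; no episodes read", path)
            return [], []
        docs = json.loads(raw)
        if not isinstance(docs, list):
            docs = [docs]
        candidates = []
        issues: list[ValidationIssue] = []
        for i, doc in enumerate(docs):
            try:
                candidates.append(EpisodeRecord.model_validate(doc))
            except Exception as exc:  # pydantic error: record-level provenance
                issues.append(ValidationIssue(f"episode[{i}]", str(exc)))
    elif format == "csv":
        candidates, issues = _read_episodes_csv(
            path, Path(trials_path) if trials_path else _trials_sidecar(path)
        )
    else:
        raise ValueError(f"unknown input format {format!r} (expected json or csv)")

    records: list[EpisodeRecord] = []
    for i, rec in enumerate(candidates):
        rec_issues = validate_episode(rec)
        if rec_issues:
            issues.extend(
                ValidationIssue(f"episode[{i}] ({rec.patient_id}).{v.field}", v.message)
                for v in rec_issues
            )
        else:
            records.append(rec)
    return records, issues


def _opt(row, key):
    v = row.get(key)
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return v


def _read_episodes_csv(
    path: Path, trials_path: Path
) -> tuple[list[EpisodeRecord], list[ValidationIssue]]:
    episodes_df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if episodes_df.empty:
        logger.warning("%s is empty; no episodes read", path)
    trials_by_patient: dict[str, list[TreatmentTrial]] = {}
    issues: list[ValidationIssue] = []
    if trials_path.exists():
        trials_df = pd.read_csv(trials_path, dtype=str, keep_default_na=False)
        for i, row in trials_df.iterrows():
            try:
                outcome_assessment = None
                if _opt(row, "outcome_instrument"):
                    outcome_assessment = SeverityAssessment(
                        instrument=row["outcome_instrument"],
                        score=int(row["outcome_score"]),
                    )
                trial = TreatmentTrial(
                    drug_name=row["drug_name"],
                    dose_mg_per_day=float(row["dose_mg_per_day"]),
                    duration_weeks=(
                        float(row["duration_weeks"]) if _opt(row, "duration_weeks") else None
                    ),
                    start_date=_opt(row, "start_date"),
                    end_date=_opt(row, "end_date"),
                    adherent=_parse_bool(row.get("adherent", "true")),
                    tolerated=_parse_bool(row.get("tolerated", "true")),
                    outcome=row.get("outcome") or "unknown",
                    instrument_outcome=outcome_assessment,
                )
                trials_by_patient.setdefault(row["patient_id"], []).append(trial)
            except Exception as exc:
                issues.append(ValidationIssue(f"{trials_path.name} row {i + 2}", str(exc)))

    records: list[EpisodeRecord] = []
    for i, row in episodes_df.iterrows():
        try:
            ect = None
            if _opt(row, "ect_n_sessions"):
                ect = ECTCourse(
                    n_sessions=int(row["ect_n_sessions"]),
                    completed=_parse_bool(row.get("ect_completed", "true")),
                    outcome=row.get("ect_outcome") or "unknown",
                )
            augmentations = tuple(
                AugmentationRecord(agent_name=name.strip(), used=True)
                for name in (row.get("augmentations") or "").split(";")
                if name.strip()
            )
            records.append(
                EpisodeRecord(
                    patient_id=row["patient_id"],
                    onset_date=row["onset_date"],
                    assessment_date=row["assessment_date"],
                    is_first_episode=_parse_bool(row.get("is_first_episode", "true")),
                    baseline_severity=SeverityAssessment(
                        instrument=row["baseline_instrument"],
                        score=int(row["baseline_score"]),
                        psychotic_features=_parse_bool(row.get("baseline_psychotic", "false")),
                    ),
                    trials=tuple(trials_by_patient.get(row["patient_id"], ())),
                    augmentations=augmentations,
                )
            )
        except Exception as exc:
            issues.append(ValidationIssue(f"{path.name} row {i + 2}", str(exc)))
    return records, issues


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in ("true", "1", "yes", "y"):
        return True
    if s in ("false", "0", "no", "n", ""):
        return False
    raise ValueError(f"not a boolean: {v!r}")


def write_episodes(records: Sequence[EpisodeRecord], path: Union[str, Path]) -> None:
    """Serialize episode records to a JSON file (round-trips with read_episodes)."""
    docs = [json.loads(r.model_dump_json()) for r in records]
    Path(path).write_text(json.dumps(docs, indent=2) + "\n")


# --- reports -----------------------------------------------------------------

_REPORT_FIELDS = [
    "patient_id", "status", "total", "band",
    "treatment_failure_score", "severity_score", "duration_score",
    "n_failed_antidepressants", "augmentation_used", "ect_used",
    "pseudo_resistance_flags", "adjudications",
]


def report_rows(results: Sequence[Result]) -> list[dict]:
    """Flatten results into report rows with identical fields in every format."""
    rows = []
    for r in results:
        flags = ";".join(f.value for f in r.pseudo_resistance_flags)
        trail = "|".join(
            f"{a.trial_index}:{a.verdict.value}:{a.reason}" for a in r.trial_adjudications
        )
        if isinstance(r, MSMResult):
            d = r.dimensions
            rows.append({
                "patient_id": r.patient_id,
                "status": "staged",
                "total": r.total,
                "band": r.band.value,
                "treatment_failure_score": d.treatment_failure_score,
                "severity_score": d.severity_score,
                "duration_score": d.duration_score,
                "n_failed_antidepressants": d.n_failed_antidepressants,
                "augmentation_used": d.augmentation_used,
                "ect_used": d.ect_used,
                "pseudo_resistance_flags": flags,
                "adjudications": trail,
            })
        else:
            rows.append({
                "patient_id": r.patient_id,
                "status": r.status,
                "total": None, "band": None,
                "treatment_failure_score": None, "severity_score": None,
                "duration_score": None, "n_failed_antidepressants": None,
                "augmentation_used": None, "ect_used": None,
                "pseudo_resistance_flags": flags,
                "adjudications": trail,
            })
    return rows


def write_report(
    results: Sequence[Result], path: Union[str, Path], format: str = "csv"
) -> None:
    """Write one row/object/worksheet per episode."""
    path = Path(path)
    rows = report_rows(results)
    if format == "json":
        path.write_text(json.dumps(rows, indent=2) + "\n")
    elif format == "csv":
        df = pd.DataFrame(rows, columns=_REPORT_FIELDS)
        df.to_csv(path, index=False)
    elif format == "text":
        path.write_text("\n".join(_worksheet(r) for r in results))
    else:
        raise ValueError(f"unknown report format {format!r} (expected json, csv or text)")


def read_report(path: Union[str, Path], format: str = "csv") -> list[dict]:
    """Parse a JSON or CSV report back into row dicts (types normalized)."""
    path = Path(path)
    if format == "json":
        return json.loads(path.read_text())
    if format != "csv":
        raise ValueError(f"unknown report format {format!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rows = []
    for _, row in df.iterrows():
        d = dict(row)
        for k in ("total", "treatment_failure_score", "severity_score",
                  "duration_score", "n_failed_antidepressants"):
            d[k] = int(d[k]) if d[k] != "" else None
        for k in ("augmentation_used", "ect_used"):
            d[k] = _parse_bool(d[k]) if d[k] != "" else None
        if d["band"] == "":
            d["band"] = None
        rows.append(d)
    return rows


def _worksheet(r: Result) -> str:
    """Clinician-readable staging worksheet for one episode."""
    lines = [f"=== MSM staging: patient {r.patient_id} ==="]
    if isinstance(r, MSMResult):
        d = r.dimensions
        lines += [
            f"Dimension 1  treatment failure : {d.treatment_failure_score}  "
            f"({d.n_failed_antidepressants} failed antidepressant(s), "
            f"augmentation {'yes' if d.augmentation_used else 'no'}, "
            f"ECT {'yes' if d.ect_used else 'no'})",
            f"Dimension 2  symptom severity  : {d.severity_score}",
            f"Dimension 3  episode duration  : {d.duration_score}",
            f"TOTAL (3-15)                   : {r.total}   band: {r.band.value.upper()}",
        ]
    else:
        lines.append("Status: NOT treatment-resistant (no counted antidepressant failure)")
    if r.pseudo_resistance_flags:
        lines.append(
            "Pseudo-resistance screening    : "
            + ", ".join(f.value for f in r.pseudo_resistance_flags)
        )
    if r.trial_adjudications:
        lines.append("Trial adjudications:")
        lines += [
            f"  [{a.trial_index}] {a.verdict.value}: {a.reason}"
            for a in r.trial_adjudications
        ]
    return "\n".join(lines) + "\n"
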