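"""Readers and writers shared by all modules.

JSON is the canonical, lossless dialect: every record type serializes
through its pydantic model, so ``parse ∘ serialize`` is the identity on
canonical documents.  CSV is a convenience dialect for flat records
(patients: one row each; sessions: one row per attempt with a session-id
column); nested structures (task logs, reports) are JSON-only.  All
timestamps are ISO-8601.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .records import PatientRecord, SpirometryAttempt, SpirometrySession


def read_patients_json(path: str | Path) -> list[PatientRecord]:
    doc = json.loads(Path(path).read_text())
    return [PatientRecord(**p) for p in doc["patients"]]


def write_patients_json(patients: Sequence[PatientRecord], path: str | Path) -> None:
    doc = {"patients": [p.model_dump(mode="json") for p in patients]}
    Path(path).write_text(json.dumps(doc, indent=2))


_PATIENT_CSV_FIELDS = list(PatientRecord.model_fields)


def read_patients_csv(path: str | Path) -> list[PatientRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        d = {k: row[k] for k in _PATIENT_CSV_FIELDS if k in df.columns and pd.notna(row[k])}
        records.append(PatientRecord(**d))
    return records


def write_patients_csv(patients: Sequence[PatientRecord], path: str | Path) -> None:
    pd.DataFrame([p.model_dump() for p in patients]).to_csv(path, index=False)


def read_session_json(path: str | Path) -> SpirometrySession:
    return SpirometrySession(**json.loads(Path(path).read_text()))


def write_session_json(session: SpirometrySession, path: str | Path) -> None:
    Path(path).write_text(session.model_dump_json(indent=2))


def read_sessions_csv(path: str | Path) -> list[SpirometrySession]:
    """One row per attempt; session metadata repeated on each row."""
    df = pd.read_csv(path, parse_dates=["session_time", "last_calibration"])
    sessions = []
    for sid, grp in df.groupby("session_id", sort=False):
        head = grp.iloc[0]
        attempts = [
            SpirometryAttempt(
                fvc_l=r["fvc_l"],
                fev1_l=r["fev1_l"],
                fet_s=r["fet_s"] if "fet_s" in grp.columns and pd.notna(r["fet_s"]) else None,
                slow_start=bool(r.get("slow_start", False)),
                early_termination=bool(r.get("early_termination", False)),
                glottis_closure=bool(r.get("glottis_closure", False)),
                variable_effort=bool(r.get("variable_effort", False)),
            )
            for _, r in grp.iterrows()
        ]
        sessions.append(
            SpirometrySession(
                session_id=str(sid),
                patient_id=str(head["patient_id"]),
                session_time=head["session_time"].to_pydatetime(),
                last_calibration=head["last_calibration"].to_pydatetime(),
                attempts=attempts,
            )
        )
    return sessions


def write_sessions_csv(sessions: Iterable[SpirometrySession], path: str | Path) -> None:
    rows = []
    for s in sessions:
        for a in s.attempts:
            rows.append(
                {
                    "session_id": s.session_id,
                    "patient_id": s.patient_id,
                    "session_time": s.session_time.isoformat(),
                    "last_calibration": s.last_calibration.isoformat(),
                    **a.model_dump(),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def export_schemas(out_dir: str | Path) -> list[Path]:
    """Write the JSON Schemas of all canonical record types."""
    from . import records
    from .cohort import CohortSpec

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    models = [
        records.PatientRecord, records.SpirometryAttempt, records.SpirometrySession,
        records.SessionVerdict, records.ScreeningResult, records.ClinicalAssessment,
        records.StagingResult, records.Notification, CohortSpec,
    ]
    for model in models:
        p = out / f"{model.__name__}.schema.json"
        p.write_text(json.dumps(model.model_json_schema(), indent=2))
        written.append(p)
    return written
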