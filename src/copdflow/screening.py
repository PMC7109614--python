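"""Opportunistic screening: invitation eligibility, questionnaire scoring,
and key-indicator clinical suspicion.

The invitation rule is the redesigned pathway's opportunistic gate: any
patient strictly over the age cut (default 40) who books an appointment for
whatever reason is invited, unless they were already screened within the
revalidation window (default 2 years).

The questionnaire itself is configuration, not code: the engine scores any
instrument definition (items, per-answer scores, cutoff).  The bundled
5-item instrument is modeled on published COPD population screeners and is
explicitly non-canonical — replace it via ``EngineConfig.instrument_path``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import yaml

from .config import EngineConfig
from .records import KEY_INDICATORS, PatientRecord, ScreeningResult


class ScoringError(ValueError):
    """An answer set that cannot be scored against the instrument."""


@dataclass(frozen=True)
class InstrumentItem:
    key: str
    text: str
    scores: Mapping[int, int]  # allowed answer -> points

    @property
    def max_points(self) -> int:
        return max(self.scores.values())


@dataclass(frozen=True)
class Instrument:
    """A screening questionnaire definition."""

    name: str
    source: str
    cutoff: int
    items: tuple[InstrumentItem, ...] = field(default_factory=tuple)

    @property
    def max_total(self) -> int:
        return sum(i.max_points for i in self.items)


def load_instrument(path: str | Path) -> Instrument:
    """Load a questionnaire definition from YAML/JSON."""
    doc = yaml.safe_load(Path(path).read_text())
    if not doc.get("source"):
        raise ValueError(f"instrument {path}: missing provenance 'source' label")
    items = tuple(
        InstrumentItem(key=i["key"], text=i.get("text", i["key"]), scores={int(k): int(v) for k, v in i["scores"].items()})
        for i in doc["items"]
    )
    if len({i.key for i in items}) != len(items):
        raise ValueError("instrument items have duplicate keys")
    return Instrument(name=doc["name"], source=doc["source"], cutoff=int(doc["cutoff"]), items=items)


@dataclass(frozen=True)
class Eligibility:
    eligible: bool
    reason: Optional[str] = None  # 'age' | 'recent_screening' | 'missing_age'


def is_eligible_for_screening(
    patient: PatientRecord | None,
    clock: dt.date,
    last_screening: Optional[dt.date] = None,
    config: Optional[EngineConfig] = None,
    *,
    age: Optional[int] = None,
) -> Eligibility:
    """Decide whether to invite a patient to opportunistic screening.

    Eligible iff age is strictly above the configured cut AND the patient
    has no screening inside the revalidation window.  ``age`` may be passed
    directly (e.g. from an appointment record without a full chart).
    """
    cfg = config or EngineConfig()
    if age is None:
        age = patient.age if patient is not None else None
    if age is None:
        return Eligibility(False, "missing_age")
    if age <= cfg.screening_age_cut:
        return Eligibility(False, "age")
    if last_screening is not None:
        if isinstance(clock, dt.datetime):
            clock = clock.date()
        if isinstance(last_screening, dt.datetime):
            last_screening = last_screening.date()
        if (clock - last_screening) <= cfg.revalidation_window:
            return Eligibility(False, "recent_screening")
    return Eligibility(True)


def score_screening(
    patient_id: str,
    answers: Mapping[str, int],
    instrument: Instrument,
    screening_date: dt.date,
) -> ScreeningResult:
    """Score a complete answer set against an instrument.

    Total is the sum of per-item points; positive iff total >= cutoff.
    Answer order never matters: items are matched by canonical key.
    """
    total = 0
    scored: dict[str, int] = {}
    for item in instrument.items:
        if item.key not in answers:
            raise ScoringError(f"missing answer for item {item.key!r}")
        ans = answers[item.key]
        if ans not in item.scores:
            raise ScoringError(
                f"answer {ans!r} out of range for item {item.key!r} (allowed {sorted(item.scores)})"
            )
        scored[item.key] = ans
        total += item.scores[ans]
    unknown = set(answers) - set(scored)
    if unknown:
        raise ScoringError(f"unknown items in answers: {sorted(unknown)}")
    return ScreeningResult(
        patient_id=patient_id,
        answers=scored,
        total=total,
        positive=total >= instrument.cutoff,
        screening_date=screening_date,
    )


@dataclass(frozen=True)
class Suspicion:
    suspected: bool
    indicators: tuple[str, ...]
    unknown_indicators: tuple[str, ...]


def key_indicator_suspicion(patient: PatientRecord, config: Optional[EngineConfig] = None) -> Suspicion:
    """Clinical suspicion from key indicators at consultation time.

    Suspicion holds iff the patient is strictly over the suspicion age cut
    and at least one key indicator (dyspnea, chronic cough, chronic sputum,
    recurrent lower-respiratory infections, risk-factor exposure, family
    history) is explicitly true.  Unknown (never-asked) flags count as
    false for the decision but are reported separately so the output
    distinguishes "absent" from "not asked".
    """
    cfg = config or EngineConfig()
    flags = patient.indicator_flags()
    unknown = tuple(k for k in KEY_INDICATORS if flags[k] is None)
    triggered = tuple(k for k in KEY_INDICATORS if flags[k] is True)
    suspected = patient.age > cfg.suspicion_age_cut and bool(triggered)
    return Suspicion(suspected=suspected, indicators=triggered, unknown_indicators=unknown)
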