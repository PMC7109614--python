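"""Severity staging: BODE/BODEx indices, CAT impact bands, referral rule.

BODE combines BMI, airflow Obstruction (FEV1 % predicted), Dyspnea (mMRC)
and Exercise (6-minute-walk distance) into a 0-10 score; BODEx replaces the
walk test with the past-year exacerbation count (0-9).  Component cut-points
are shipped as an auditable CSV data file with a provenance label, never
hard-coded.  The mapping from index score to the four severity levels (mild,
moderate, severe, very severe) and from CAT to the four impact levels is a
configurable band table; the defaults are quartile-style and explicitly
non-canonical.  An FEV1-%-predicted banding (GOLD-style grades) is available
as an alternative severity driver via ``index_precedence='fev1'``.

Referral to a specialist fires when severity is severe or very severe, or on
frequent exacerbations (default >=2/yr moderate or >=1 hospitalization); a
flagged referral must carry a complete structured report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .config import EngineConfig
from .records import ClinicalAssessment, ImpactLevel, ReferralReport, SeverityLevel, StagingResult


class StagingError(ValueError):
    pass


class BodeUnavailable(StagingError):
    """BODE cannot be computed (no 6-minute-walk distance recorded)."""


class ReportIncomplete(StagingError):
    """A flagged referral is missing a mandatory report field."""


class IndexCutpoints:
    """Component cut-point bands loaded from the bundled (or a user) CSV.

    Convention: a value v earns the points of the unique row of its
    component with min < v <= max (blank bound = unbounded).
    """

    def __init__(self, table: pd.DataFrame, source: str):
        self.source = source
        self._bands: dict[tuple[str, str], list[tuple[float, float, int]]] = {}
        for (index, component), grp in table.groupby(["index", "component"]):
            bands = [
                (
                    -math.inf if pd.isna(r["min"]) else float(r["min"]),
                    math.inf if pd.isna(r["max"]) else float(r["max"]),
                    int(r["points"]),
                )
                for _, r in grp.iterrows()
            ]
            bands.sort()
            for (_, hi_a, _), (lo_b, _, _) in zip(bands, bands[1:]):
                if hi_a != lo_b:
                    raise ValueError(f"{index}/{component}: bands not contiguous at {hi_a}")
            self._bands[(index, component)] = bands

    @classmethod
    def from_csv(cls, path: str | Path) -> "IndexCutpoints":
        path = Path(path)
        with open(path) as fh:
            first = fh.readline()
        if not first.startswith("#") or "source:" not in first:
            raise ValueError(f"{path}: cut-point file must start with a '# source:' provenance line")
        return cls(pd.read_csv(path, comment="#"), source=first.lstrip("#").strip())

    def points(self, index: str, component: str, value: float) -> int:
        try:
            bands = self._bands[(index, component)]
        except KeyError:
            raise StagingError(f"no cut-points for {index}/{component}") from None
        for lo, hi, pts in bands:
            if lo < value <= hi:
                return pts
        raise StagingError(f"{index}/{component}: value {value} outside all bands")


def _default_cutpoints(config: Optional[EngineConfig]) -> IndexCutpoints:
    cfg = config or EngineConfig()
    return IndexCutpoints.from_csv(cfg.cutpoints_path)


def bode_score(
    assessment: ClinicalAssessment, cutpoints: Optional[IndexCutpoints] = None, config: Optional[EngineConfig] = None
) -> tuple[int, dict[str, int]]:
    """BODE index (0-10) with per-component points.

    Raises :class:`BodeUnavailable` when no 6MWD is recorded — callers fall
    back to BODEx.
    """
    if assessment.six_mwd_m is None:
        raise BodeUnavailable("six_mwd_m missing; use BODEx")
    cp = cutpoints or _default_cutpoints(config)
    parts = {
        "bmi": cp.points("bode", "bmi", assessment.bmi),
        "fev1_pct_pred": cp.points("bode", "fev1_pct_pred", assessment.fev1_pct_pred),
        "mmrc": cp.points("bode", "mmrc", assessment.mmrc),
        "six_mwd_m": cp.points("bode", "six_mwd_m", assessment.six_mwd_m),
    }
    return sum(parts.values()), parts


def bodex_score(
    assessment: ClinicalAssessment, cutpoints: Optional[IndexCutpoints] = None, config: Optional[EngineConfig] = None
) -> tuple[int, dict[str, int]]:
    """BODEx index (0-9): exercise replaced by the exacerbation count (0-2)."""
    cp = cutpoints or _default_cutpoints(config)
    parts = {
        "bmi": cp.points("bodex", "bmi", assessment.bmi),
        "fev1_pct_pred": cp.points("bodex", "fev1_pct_pred", assessment.fev1_pct_pred),
        "mmrc": cp.points("bodex", "mmrc", assessment.mmrc),
        "exacerbations": cp.points("bodex", "exacerbations", assessment.exacerbations_last_year),
    }
    return sum(parts.values()), parts


def _band_lookup(bands: list[tuple[int, int, str]], score: float, name: str) -> str:
    for lo, hi, level in bands:
        if lo <= score <= hi:
            return level
    raise StagingError(f"{name}: score {score} outside the band table")


def severity_level(score: float, which: str, config: Optional[EngineConfig] = None) -> SeverityLevel:
    """Map an index score to mild/moderate/severe/very severe.

    ``which`` selects the band table: 'bode', 'bodex' or 'fev1' (% predicted,
    GOLD-style descending bands).
    """
    cfg = config or EngineConfig()
    tables = {
        "bode": cfg.severity_bands_bode,
        "bodex": cfg.severity_bands_bodex,
        "fev1": cfg.severity_bands_fev1,
    }
    if which not in tables:
        raise StagingError(f"unknown severity index {which!r}")
    if which == "fev1":
        # % predicted is continuous; the integer bands read as [50, 80) etc.
        score = math.floor(score)
    return _band_lookup(tables[which], score, f"severity_bands_{which}")  # type: ignore[return-value]


def impact_level(cat: int, config: Optional[EngineConfig] = None) -> ImpactLevel:
    """Map a CAT total (0-40) to low/moderate/high/very high impact."""
    cfg = config or EngineConfig()
    if not (0 <= cat <= 40):
        raise StagingError(f"CAT score {cat} outside [0, 40]")
    return _band_lookup(cfg.impact_bands_cat, cat, "impact_bands_cat")  # type: ignore[return-value]


MANDATORY_REPORT_FIELDS = ("scores", "spirometry_summary", "exacerbation_history")


@dataclass(frozen=True)
class ReferralDecision:
    refer: bool
    reasons: tuple[str, ...]


def referral_decision(
    severity: SeverityLevel, assessment: ClinicalAssessment, config: Optional[EngineConfig] = None
) -> ReferralDecision:
    """Specialist referral: severe/very severe disease or frequent exacerbations."""
    cfg = config or EngineConfig()
    reasons = []
    if severity in ("severe", "very severe"):
        reasons.append(f"severity_{severity.replace(' ', '_')}")
    if assessment.exacerbations_last_year >= cfg.frequent_exacerbation_threshold:
        reasons.append("frequent_exacerbations")
    if assessment.hospitalizations_last_year >= cfg.hospitalization_referral_threshold:
        reasons.append("hospitalizations")
    return ReferralDecision(refer=bool(reasons), reasons=tuple(reasons))


def build_referral_report(
    assessment: ClinicalAssessment,
    scores: Mapping[str, int],
    spirometry_summary: str,
    comorbidity_notes: str = "",
) -> ReferralReport:
    """Assemble the structured referral report; rejects missing mandatory fields."""
    fields = {
        "scores": dict(scores),
        "spirometry_summary": spirometry_summary,
        "exacerbation_history": (
            f"{assessment.exacerbations_last_year} exacerbation(s), "
            f"{assessment.hospitalizations_last_year} hospitalization(s) in the past year"
        ),
    }
    for name in MANDATORY_REPORT_FIELDS:
        if not fields[name]:
            raise ReportIncomplete(f"mandatory referral report field missing: {name}")
    return ReferralReport(patient_id=assessment.patient_id, comorbidity_notes=comorbidity_notes, **fields)


def stage_patient(
    assessment: ClinicalAssessment,
    cutpoints: Optional[IndexCutpoints] = None,
    config: Optional[EngineConfig] = None,
    spirometry_summary: str = "",
) -> StagingResult:
    """Full staging pipeline: indices → severity + impact → referral (+ report).

    Index precedence is configurable; the default prefers BODE when a 6MWD
    is recorded (the richer, exercise-inclusive path) and falls back to
    BODEx otherwise.
    """
    cfg = config or EngineConfig()
    cp = cutpoints or _default_cutpoints(cfg)
    bodex, _ = bodex_score(assessment, cp)
    bode: Optional[int] = None
    try:
        bode, _ = bode_score(assessment, cp)
    except BodeUnavailable:
        pass

    if cfg.index_precedence == "fev1":
        driving, score = "fev1", assessment.fev1_pct_pred
    elif cfg.index_precedence == "bode" and bode is not None:
        driving, score = "bode", bode
    else:
        driving, score = "bodex", bodex
    severity = severity_level(score, driving, cfg)
    impact = impact_level(assessment.cat_score, cfg)
    decision = referral_decision(severity, assessment, cfg)

    report = None
    if decision.refer:
        scores: dict[str, int] = {"bodex": bodex}
        if bode is not None:
            scores["bode"] = bode
        report = build_referral_report(
            assessment,
            scores=scores,
            spirometry_summary=spirometry_summary or "spirometry summary not attached",
        )
    return StagingResult(
        patient_id=assessment.patient_id,
        bode=bode,
        bodex=bodex,
        driving_index=driving,  # type: ignore[arg-type]
        severity=severity,
        impact=impact,
        refer=decision.refer,
        referral_reasons=list(decision.reasons),
        report=report,
    )
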