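"""Canonical record types flowing through the diagnostic process.

All records are pydantic models so that every reader (JSON, CSV, CLI input)
funnels through one validated schema.  Symptom flags are tri-state:
``True`` / ``False`` are explicit clinical answers, ``None`` means the
question was never asked — downstream logic must not silently conflate
"absent" with "unknown".
"""

from __future__ import annotations

import datetime as dt
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

Sex = Literal["male", "female"]

#: canonical key-indicator symptom/history flags used for clinical suspicion
KEY_INDICATORS = (
    "dyspnea",
    "chronic_cough",
    "chronic_sputum",
    "recurrent_infections",
    "risk_factor_exposure",
    "family_history_copd",
)


class PatientRecord(BaseModel):
    """Demographics, anthropometrics and history for one patient."""

    model_config = ConfigDict(validate_assignment=True)

    patient_id: str
    age: int = Field(ge=0, le=130)
    sex: Sex
    height_cm: float = Field(gt=0)
    weight_kg: float = Field(gt=0)
    ethnic_group: str = "caucasian"
    smoking_status: Literal["never", "ex", "current"] = "never"
    pack_years: float = Field(default=0.0, ge=0)
    # tri-state symptom flags; None == not asked
    dyspnea: Optional[bool] = None
    chronic_cough: Optional[bool] = None
    chronic_sputum: Optional[bool] = None
    recurrent_infections: Optional[bool] = None
    risk_factor_exposure: Optional[bool] = None
    family_history_copd: Optional[bool] = None

    @property
    def bmi(self) -> float:
        """Body mass index in kg/m²."""
        h = self.height_cm / 100.0
        return self.weight_kg / (h * h)

    def indicator_flags(self) -> dict[str, Optional[bool]]:
        return {k: getattr(self, k) for k in KEY_INDICATORS}


class SpirometryAttempt(BaseModel):
    """One forced expiratory maneuver.

    Curve-shape acceptability flags (slow start, glottis closure, variable
    effort) are operator judgements entered at the bedside; only
    ``early_termination`` can also be derived, from the forced expiratory
    time when the device reports it.
    """

    fvc_l: float = Field(gt=0.2, lt=10.0, description="forced vital capacity, liters")
    fev1_l: float = Field(gt=0.0, description="FEV1, liters")
    fet_s: Optional[float] = Field(default=None, gt=0, description="forced expiratory time, s")
    slow_start: bool = False
    early_termination: bool = False
    glottis_closure: bool = False
    variable_effort: bool = False

    @model_validator(mode="after")
    def _fev1_not_above_fvc(self) -> "SpirometryAttempt":
        if self.fev1_l > self.fvc_l:
            raise ValueError(f"FEV1 {self.fev1_l} L exceeds FVC {self.fvc_l} L")
        return self

    @property
    def flagged(self) -> bool:
        return self.slow_start or self.early_termination or self.glottis_closure or self.variable_effort


class SpirometrySession(BaseModel):
    """A spirometry visit: device calibration state plus the attempt set."""

    session_id: str
    patient_id: str
    session_time: dt.datetime
    last_calibration: dt.datetime
    attempts: list[SpirometryAttempt] = Field(default_factory=list)


class SessionVerdict(BaseModel):
    """Derived interpretation of a session (produced, never hand-entered)."""

    session_id: str
    calibrated: bool
    acceptable_attempts: int
    reproducible: bool
    reason: Optional[str] = None
    delta_fvc_l: Optional[float] = None
    delta_fev1_l: Optional[float] = None
    valid: bool
    best_fvc_l: Optional[float] = None
    best_fev1_l: Optional[float] = None
    ratio: Optional[float] = None
    threshold_mode: Optional[Literal["fixed", "lln"]] = None
    threshold_used: Optional[float] = None
    obstruction: Optional[bool] = None


class ScreeningResult(BaseModel):
    """Scored screening questionnaire."""

    patient_id: str
    answers: dict[str, int]
    total: int
    positive: bool
    screening_date: dt.date


class ClinicalAssessment(BaseModel):
    """Inputs to severity and impact staging."""

    patient_id: str
    bmi: float = Field(gt=0)
    fev1_pct_pred: float = Field(gt=0, description="FEV1 as % of predicted")
    mmrc: int = Field(ge=0, le=4, description="mMRC dyspnea grade")
    exacerbations_last_year: int = Field(ge=0)
    hospitalizations_last_year: int = Field(default=0, ge=0)
    cat_score: int = Field(ge=0, le=40, description="COPD Assessment Test total")
    six_mwd_m: Optional[float] = Field(default=None, ge=0, description="6-minute walk distance, m")


SeverityLevel = Literal["mild", "moderate", "severe", "very severe"]
ImpactLevel = Literal["low", "moderate", "high", "very high"]


class ReferralReport(BaseModel):
    """Structured report accompanying a specialist referral."""

    patient_id: str
    scores: dict[str, int]
    spirometry_summary: str
    exacerbation_history: str
    comorbidity_notes: str = ""


class StagingResult(BaseModel):
    """Severity/impact staging outcome plus the referral decision."""

    patient_id: str
    bode: Optional[int] = Field(default=None, ge=0, le=10)
    bodex: int = Field(ge=0, le=9)
    driving_index: Literal["bode", "bodex", "fev1"]
    severity: SeverityLevel
    impact: ImpactLevel
    refer: bool
    referral_reasons: list[str] = Field(default_factory=list)
    report: Optional[ReferralReport] = None


NotificationKind = Literal["screening_invite", "screening_positive_alert", "appointment_reminder"]


class Notification(BaseModel):
    """An outbound message artifact (the engine never sends anything)."""

    recipient_role: Literal["patient", "doctor"]
    kind: NotificationKind
    scheduled_time: dt.datetime
    payload_key: str
    patient_id: str
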