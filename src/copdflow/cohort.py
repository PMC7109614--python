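"""Synthetic patient cohorts with known obstruction ground truth.

The generator is the fixture factory for the whole engine: patients,
appointment streams, screening answers, three-attempt spirometry sessions
and ground-truth labels, all deterministic given the cohort seed.  Each
patient draws from an independent stream keyed by (seed, patient index), so
extending a cohort never reshuffles existing patients.

True FEV1/FVC ratios are generated *relative to each patient's own lower
limit of normal*: obstructed patients sit strictly below their LLN,
non-obstructed strictly above, with a minimum clearance of 0.01 so that the
0.01 L recording lattice can never flip a noise-free call.  This makes the
fixed-0.7-versus-LLN discordance band exercisable by construction.

Screening answers are sampled to hit the spec'd sensitivity/specificity in
expectation: the intended positivity is drawn per patient, then an answer
set scoring on the intended side of the instrument cutoff is built.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field

from .config import EngineConfig
from .records import ClinicalAssessment, PatientRecord, SpirometryAttempt, SpirometrySession
from .screening import Instrument, is_eligible_for_screening, key_indicator_suspicion, load_instrument, score_screening
from .spirometry import ReferenceEquationSet, interpret_session
from .staging import IndexCutpoints, severity_level, stage_patient
from .process import (
    Appointment,
    ProcessInstance,
    ProcessModel,
    advance,
    default_model,
    schedule_reminder,
    start_instance,
)


class CohortSpec(BaseModel):
    """Parameters of a synthetic cohort (all probabilities in [0, 1])."""

    n: int = Field(ge=1)
    seed: int = 0
    age_min: int = 41
    age_max: int = 85
    female_fraction: float = Field(default=0.5, ge=0, le=1)
    smoking_prevalence: float = Field(default=0.6, ge=0, le=1)
    obstruction_prevalence: float = Field(default=0.3, ge=0, le=1)
    #: mean/sd of the true-ratio clearance below (obstructed) / above (normal) the patient's LLN
    obstructed_ratio_gap_mean: float = Field(default=0.08, ge=0)
    obstructed_ratio_gap_sd: float = Field(default=0.04, ge=0)
    normal_ratio_gap_mean: float = Field(default=0.07, ge=0)
    normal_ratio_gap_sd: float = Field(default=0.03, ge=0)
    attempt_noise_sd_l: float = Field(default=0.05, ge=0, description="within-session noise sigma, L")
    screening_sensitivity: float = Field(default=0.9, ge=0, le=1)
    screening_specificity: float = Field(default=0.85, ge=0, le=1)
    no_show_probability: float = Field(default=0.1, ge=0, le=1)
    six_mwd_available_probability: float = Field(default=0.7, ge=0, le=1)
    start_date: dt.datetime = dt.datetime(2026, 1, 5, 9, 0)
    group_weights: dict[str, float] = Field(
        default_factory=lambda: {"caucasian": 0.8, "african_american": 0.1, "mexican_american": 0.1}
    )


@dataclass(frozen=True)
class GroundTruthLabel:
    patient_id: str
    obstructed: bool
    severity_stratum: str  # FEV1-%-predicted band of the true values


@dataclass
class CohortData:
    spec: CohortSpec
    patients: list[PatientRecord]
    appointments: list[Appointment]
    screening_answers: dict[str, dict[str, int]]
    sessions: dict[str, SpirometrySession]
    assessments: dict[str, ClinicalAssessment]
    labels: dict[str, GroundTruthLabel]
    no_show: dict[str, bool]
    request_times: dict[str, dt.datetime]
    true_values: dict[str, tuple[float, float]] = field(default_factory=dict)  # pid -> (FVC, FEV1)


def _forced_answers(rng: np.random.Generator, instrument: Instrument, positive: bool) -> dict[str, int]:
    """Random answers nudged to land on the requested side of the cutoff."""
    answers = {i.key: int(rng.choice(sorted(i.scores))) for i in instrument.items}

    def total() -> int:
        return sum(i.scores[answers[i.key]] for i in instrument.items)

    items = list(instrument.items)
    rng.shuffle(items)  # which items get bumped varies per patient
    for item in items:
        if positive and total() < instrument.cutoff:
            answers[item.key] = max(item.scores, key=item.scores.get)
        elif not positive and total() >= instrument.cutoff:
            answers[item.key] = min(item.scores, key=item.scores.get)
    assert (total() >= instrument.cutoff) == positive
    return answers


def _make_attempts(
    rng: np.random.Generator, true_fvc: float, true_fev1: float, sigma: float, k: int = 3
) -> list[SpirometryAttempt]:
    attempts = []
    for _ in range(k):
        fvc = round(max(0.5, true_fvc + rng.normal(0, sigma)) if sigma > 0 else true_fvc, 2)
        fev1 = round(max(0.2, true_fev1 + rng.normal(0, sigma)) if sigma > 0 else true_fev1, 2)
        fev1 = min(fev1, fvc)
        attempts.append(SpirometryAttempt(fvc_l=fvc, fev1_l=fev1, fet_s=8.0))
    return attempts


def generate_cohort(
    spec: CohortSpec,
    config: Optional[EngineConfig] = None,
    equations: Optional[ReferenceEquationSet] = None,
    instrument: Optional[Instrument] = None,
) -> CohortData:
    """Generate a full cohort; byte-identical for identical specs."""
    cfg = config or EngineConfig()
    eqs = equations or ReferenceEquationSet.from_csv(cfg.equations_path)
    instr = instrument or load_instrument(cfg.instrument_path)
    groups = sorted(spec.group_weights)
    gw = np.array([spec.group_weights[g] for g in groups], dtype=float)
    gw = gw / gw.sum()

    data = CohortData(
        spec=spec, patients=[], appointments=[], screening_answers={}, sessions={},
        assessments={}, labels={}, no_show={}, request_times={},
    )
    for i in range(spec.n):
        rng = np.random.default_rng([spec.seed, i])
        pid = f"pt{i:05d}"
        sex = "female" if rng.random() < spec.female_fraction else "male"
        age = int(rng.integers(spec.age_min, spec.age_max + 1))
        height = float(np.clip(rng.normal(175 if sex == "male" else 162, 7), 145, 198))
        bmi = float(np.clip(rng.normal(27, 4), 17, 42))
        weight = bmi * (height / 100) ** 2
        group = groups[int(rng.choice(len(groups), p=gw))]
        obstructed = bool(rng.random() < spec.obstruction_prevalence)
        smoker = rng.random() < (0.85 if obstructed else spec.smoking_prevalence)
        patient = PatientRecord(
            patient_id=pid, age=age, sex=sex, height_cm=round(height, 1), weight_kg=round(weight, 1),
            ethnic_group=group,
            smoking_status="current" if smoker else "never",
            pack_years=round(float(rng.uniform(15, 60)) if smoker else 0.0, 1),
            dyspnea=bool(rng.random() < (0.85 if obstructed else 0.15)),
            chronic_cough=bool(rng.random() < (0.7 if obstructed else 0.2)),
            chronic_sputum=bool(rng.random() < (0.5 if obstructed else 0.1)),
            recurrent_infections=bool(rng.random() < (0.3 if obstructed else 0.05)),
            risk_factor_exposure=smoker,
            family_history_copd=bool(rng.random() < 0.1),
        )
        data.patients.append(patient)

        pred_ratio, lln, pred_fev1 = eqs.evaluate(patient)
        if obstructed:
            gap = max(0.01, float(rng.normal(spec.obstructed_ratio_gap_mean, spec.obstructed_ratio_gap_sd)))
            true_ratio = max(0.25, lln - gap)
        else:
            gap = max(0.01, float(rng.normal(spec.normal_ratio_gap_mean, spec.normal_ratio_gap_sd)))
            true_ratio = min(0.95, lln + gap)
        true_fvc = (pred_fev1 / pred_ratio) * float(np.clip(rng.normal(1.0, 0.08), 0.7, 1.3))
        true_fev1 = true_ratio * true_fvc
        data.true_values[pid] = (true_fvc, true_fev1)

        request_time = spec.start_date + dt.timedelta(hours=float(rng.uniform(0, 8)))
        appt_time = spec.start_date + dt.timedelta(days=int(rng.integers(2, 21)), hours=int(rng.integers(0, 8)))
        data.request_times[pid] = request_time
        data.appointments.append(Appointment(patient_id=pid, age=age, appointment_time=appt_time))
        data.no_show[pid] = bool(rng.random() < spec.no_show_probability)

        if obstructed:
            want_positive = rng.random() < spec.screening_sensitivity
        else:
            want_positive = rng.random() >= spec.screening_specificity
        data.screening_answers[pid] = _forced_answers(rng, instr, want_positive)

        session_time = appt_time + dt.timedelta(minutes=30)
        data.sessions[pid] = SpirometrySession(
            session_id=f"sp-{pid}",
            patient_id=pid,
            session_time=session_time,
            last_calibration=session_time - dt.timedelta(hours=2),
            attempts=_make_attempts(rng, true_fvc, true_fev1, spec.attempt_noise_sd_l),
        )

        fev1_pct = 100.0 * true_fev1 / pred_fev1
        stratum = severity_level(fev1_pct, "fev1", cfg) if obstructed else "none"
        data.labels[pid] = GroundTruthLabel(patient_id=pid, obstructed=obstructed, severity_stratum=stratum)
        mmrc = int(np.clip(rng.poisson(2.2 if obstructed else 0.4), 0, 4))
        exac = int(rng.poisson(1.2 if obstructed else 0.1))
        hosp = int(rng.poisson(0.3 if obstructed else 0.02))
        cat = int(np.clip(rng.normal(18 if obstructed else 7, 6), 0, 40))
        data.assessments[pid] = ClinicalAssessment(
            patient_id=pid,
            bmi=round(patient.bmi, 1),
            fev1_pct_pred=round(max(10.0, fev1_pct), 1),
            mmrc=mmrc,
            exacerbations_last_year=exac,
            hospitalizations_last_year=hosp,
            cat_score=cat,
            six_mwd_m=round(float(np.clip(rng.normal(420 - 40 * mmrc, 60), 50, 700)), 0)
            if rng.random() < spec.six_mwd_available_probability
            else None,
        )
    return data


@dataclass
class ReplayResult:
    instances: dict[str, ProcessInstance]
    engine_calls: dict[str, Optional[bool]]  # None == no call (no-show)
    confusion: dict[str, int]  # tp / fp / fn / tn over patients with a call
    sensitivity: Optional[float]
    specificity: Optional[float]
    screening_uptake: float
    referral_rate: float
    first_session_invalid_fraction: float
    mean_time_to_terminal_days: float

    @property
    def n_called(self) -> int:
        return sum(self.confusion.values())


def end_to_end_replay(
    cohort: CohortData,
    config: Optional[EngineConfig] = None,
    model: Optional[ProcessModel] = None,
    max_session_retries: int = 2,
) -> ReplayResult:
    """Drive every cohort patient through the full process to a terminal state.

    The walk mirrors the clinical pathway: sweep-eligibility, screening,
    reminder, consultation (or no-show timeout), suspicion, spirometry with
    calibration check and up to ``max_session_retries`` repeat sessions on a
    reproducibility failure (the final repeat is performed noise-free — the
    patient eventually completes a technically adequate session, which keeps
    every instance terminal), differential confirmation, staging, and
    referral or primary-care treatment.  Returns the confusion of engine
    obstruction calls against ground truth plus process metrics.
    """
    cfg = config or EngineConfig()
    model = model or default_model(cfg)
    eqs = ReferenceEquationSet.from_csv(cfg.equations_path)
    instr = load_instrument(cfg.instrument_path)
    cutpoints = IndexCutpoints.from_csv(cfg.cutpoints_path)

    instances: dict[str, ProcessInstance] = {}
    calls: dict[str, Optional[bool]] = {}
    invited = screened = 0
    referred = 0
    first_invalid = 0
    spirometried = 0
    tt_days: list[float] = []

    for patient, appt in zip(cohort.patients, cohort.appointments):
        pid = patient.patient_id
        label = cohort.labels[pid]
        t = cohort.request_times[pid]
        inst = start_instance(model, f"run-{pid}", pid, t)
        instances[pid] = inst
        advance(inst, "appointment_registered", t, model, config=cfg)
        elig = is_eligible_for_screening(patient, t.date(), None, cfg)
        advance(
            inst, "eligibility_checked", t, model,
            payload={"eligible": elig.eligible, "appointment_time": appt.appointment_time}, config=cfg,
        )
        inst.notifications.append(schedule_reminder(pid, appt.appointment_time, cfg))
        if elig.eligible:
            invited += 1
            t += dt.timedelta(hours=12)
            result = score_screening(pid, cohort.screening_answers[pid], instr, t.date())
            screened += 1
            advance(inst, "screening_done", t, model, payload={"screening_positive": result.positive}, config=cfg)
            if result.positive:
                advance(inst, "suspicion_logged", t, model, config=cfg)

        if cohort.no_show[pid]:
            advance(inst, "no_show_timeout", appt.appointment_time + cfg.no_show_window, model, config=cfg)
            calls[pid] = None
            tt_days.append((inst.log[-1].entry - cohort.request_times[pid]).total_seconds() / 86400)
            continue

        t = appt.appointment_time
        advance(inst, "consultation_started", t, model, config=cfg)
        suspected = bool(inst.payload.get("screening_positive")) or key_indicator_suspicion(patient, cfg).suspected
        advance(inst, "evaluation_done", t, model, payload={"suspected": suspected}, config=cfg)
        if not suspected:
            calls[pid] = False
            tt_days.append((t - cohort.request_times[pid]).total_seconds() / 86400)
            continue

        session = cohort.sessions[pid]
        t = session.session_time
        calibrated = session.last_calibration <= t and (t - session.last_calibration) <= cfg.calibration_max_age
        advance(inst, "calibration_checked", t, model, payload={"calibrated": calibrated}, config=cfg)
        if not calibrated:
            advance(inst, "calibration_performed", t, model, config=cfg)
            session = session.model_copy(update={"last_calibration": t})
        spirometried += 1

        verdict = None
        for retry in range(max_session_retries + 1):
            advance(inst, "attempts_recorded", t, model, config=cfg)
            verdict = interpret_session(session, patient, eqs, cfg)
            if retry == 0 and not verdict.valid:
                first_invalid += 1
            if verdict.valid:
                break
            advance(inst, "session_assessed", t, model, payload={"session_valid": False}, config=cfg)
            t += dt.timedelta(minutes=15)
            rng = np.random.default_rng([cohort.spec.seed, int(pid.lstrip("pt") or 0), 1000 + retry])
            sigma = 0.0 if retry == max_session_retries - 1 else cohort.spec.attempt_noise_sd_l
            true_fvc, true_fev1 = cohort.true_values[pid]
            session = session.model_copy(update={"attempts": _make_attempts(rng, true_fvc, true_fev1, sigma)})
        assert verdict is not None and verdict.valid
        obstructed = bool(verdict.obstruction)
        advance(
            inst, "session_assessed", t, model,
            payload={"session_valid": True, "obstructed": obstructed}, config=cfg,
        )
        calls[pid] = obstructed
        if not obstructed:
            tt_days.append((t - cohort.request_times[pid]).total_seconds() / 86400)
            continue

        t += dt.timedelta(hours=2)
        advance(inst, "tests_reviewed", t, model, config=cfg)
        advance(inst, "differential_done", t, model, payload={"copd_confirmed": True}, config=cfg)
        staging = stage_patient(
            cohort.assessments[pid], cutpoints, cfg,
            spirometry_summary=f"ratio {verdict.ratio:.3f} < {verdict.threshold_used:.3f} ({verdict.threshold_mode})",
        )
        advance(inst, "staging_done", t, model, payload={"refer": staging.refer}, config=cfg)
        if staging.refer:
            referred += 1
            advance(inst, "report_completed", t + dt.timedelta(minutes=20), model, config=cfg)
        else:
            advance(inst, "treatment_defined", t + dt.timedelta(minutes=20), model, config=cfg)
        tt_days.append((inst.log[-1].entry - cohort.request_times[pid]).total_seconds() / 86400)

    stuck = [pid for pid, inst in instances.items() if not inst.is_terminal(model)]
    if stuck:
        raise RuntimeError(f"instances stuck non-terminal: {stuck[:5]}")

    tp = sum(1 for pid, c in calls.items() if c is True and cohort.labels[pid].obstructed)
    fp = sum(1 for pid, c in calls.items() if c is True and not cohort.labels[pid].obstructed)
    fn = sum(1 for pid, c in calls.items() if c is False and cohort.labels[pid].obstructed)
    tn = sum(1 for pid, c in calls.items() if c is False and not cohort.labels[pid].obstructed)
    n_diag = sum(1 for c in calls.values() if c is True)
    return ReplayResult(
        instances=instances,
        engine_calls=calls,
        confusion={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        sensitivity=tp / (tp + fn) if (tp + fn) else None,
        specificity=tn / (tn + fp) if (tn + fp) else None,
        screening_uptake=screened / invited if invited else 0.0,
        referral_rate=referred / n_diag if n_diag else 0.0,
        first_session_invalid_fraction=first_invalid / spirometried if spirometried else 0.0,
        mean_time_to_terminal_days=float(np.mean(tt_days)) if tt_days else 0.0,
    )
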