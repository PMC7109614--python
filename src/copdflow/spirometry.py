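"""Spirometry quality control and interpretation.

A session is *valid* when the device is calibrated and the attempt set meets
the reproducibility criterion: with at least three acceptable attempts, the
difference between the two best FVC values and between the two best FEV1
values must each be <= 0.15 L.  Best FVC and best FEV1 are per-parameter
maxima over acceptable attempts and may come from different maneuvers.

Obstruction is called on the ratio best FEV1 / best FVC, either against the
fixed 0.7 cut (guideline convention) or against a demographic lower limit of
normal (LLN) computed from a reference equation set for the patient's age,
sex and ancestry group.  The fixed cut is known to overcall obstruction in
the elderly, whose normal ratio drifts below 0.7 — the LLN mode is the
engine's default.

Volumes are treated as recorded on a 0.01 L lattice (spirometers report
centiliters); reproducibility deltas are therefore rounded to 0.001 L before
comparison so the inclusive 0.15 L boundary is honored exactly.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .config import EngineConfig
from .records import PatientRecord, SessionVerdict, SpirometryAttempt, SpirometrySession


class SpirometryError(ValueError):
    pass


class RangeError(SpirometryError):
    """Patient outside an equation set's validated age/height range."""


class MappingError(SpirometryError):
    """Ethnic-group label with no coefficient row."""


def check_calibration(last_calibration: dt.datetime, clock: dt.datetime, max_age: Optional[dt.timedelta] = None) -> bool:
    """True iff the device was calibrated within ``max_age`` (default 24 h)."""
    if max_age is None:
        max_age = EngineConfig().calibration_max_age
    if last_calibration > clock:
        raise SpirometryError("last_calibration is in the future")
    return (clock - last_calibration) <= max_age


def flag_attempt_quality(attempt: SpirometryAttempt, config: Optional[EngineConfig] = None) -> SpirometryAttempt:
    """Return the attempt with derivable quality flags applied.

    Only ``early_termination`` is computable here (forced expiratory time
    below the configured minimum, default 6 s, when the device reports FET).
    The curve-shape flags — slow start, glottis closure, variable effort —
    are operator judgements and pass through unchanged.
    """
    cfg = config or EngineConfig()
    if attempt.fet_s is not None and attempt.fet_s < cfg.min_fet_s:
        return attempt.model_copy(update={"early_termination": True})
    return attempt


def acceptable_attempts(attempts: Sequence[SpirometryAttempt], config: Optional[EngineConfig] = None) -> list[SpirometryAttempt]:
    """Attempts with no quality flag after derivable flags are applied."""
    cfg = config or EngineConfig()
    flagged = [flag_attempt_quality(a, cfg) for a in attempts]
    return [a for a in flagged if not a.flagged]


@dataclass(frozen=True)
class Reproducibility:
    reproducible: bool
    reason: Optional[str] = None  # 'insufficient_attempts' when < minimum
    delta_fvc_l: Optional[float] = None
    delta_fev1_l: Optional[float] = None


def check_reproducibility(
    attempts: Sequence[SpirometryAttempt], config: Optional[EngineConfig] = None
) -> Reproducibility:
    """Apply the two-best-values rule over acceptable attempts.

    Requires at least ``min_acceptable_attempts`` (default 3) acceptable
    maneuvers; then both (max FVC − second FVC) and (max FEV1 − second FEV1)
    must be <= the threshold (default 0.15 L, inclusive).  With more than
    three attempts the same two-best rule applies — extra maneuvers can only
    help.  Deltas are rounded to 0.001 L (see module docstring).
    """
    cfg = config or EngineConfig()
    acc = acceptable_attempts(attempts, cfg)
    if len(acc) < cfg.min_acceptable_attempts:
        return Reproducibility(False, reason="insufficient_attempts")
    fvcs = sorted((a.fvc_l for a in acc), reverse=True)
    fev1s = sorted((a.fev1_l for a in acc), reverse=True)
    d_fvc = round(fvcs[0] - fvcs[1], 3)
    d_fev1 = round(fev1s[0] - fev1s[1], 3)
    ok = d_fvc <= cfg.reproducibility_threshold_l and d_fev1 <= cfg.reproducibility_threshold_l
    return Reproducibility(ok, delta_fvc_l=d_fvc, delta_fev1_l=d_fev1)


def select_best(attempts: Sequence[SpirometryAttempt]) -> tuple[float, float]:
    """Per-parameter maxima (best FVC, best FEV1), possibly from different attempts."""
    if not attempts:
        raise SpirometryError("no_acceptable_attempts")
    return max(a.fvc_l for a in attempts), max(a.fev1_l for a in attempts)


class ReferenceEquationSet:
    """Per-(sex, ancestry-group) coefficient rows mapping (age, height) to
    predicted FEV1 and the FEV1/FVC ratio with its lower limit of normal.

    Rows may define the ratio LLN either by an explicit LLN intercept
    (sharing the age slope) or by a standard error of estimate, in which
    case LLN = predicted − 1.645 × SEE.  Evaluation outside a row's
    validated age/height range raises :class:`RangeError` — the set never
    extrapolates.
    """

    def __init__(self, table: pd.DataFrame, source: str):
        required = {
            "sex", "group", "age_min", "age_max", "height_min_cm", "height_max_cm",
            "ratio_intercept", "ratio_age", "fev1_intercept", "fev1_age", "fev1_age2", "fev1_ht2",
        }
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"equation table missing columns: {sorted(missing)}")
        self.table = table.set_index(["sex", "group"], verify_integrity=True)
        self.source = source

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceEquationSet":
        path = Path(path)
        with open(path) as fh:
            first = fh.readline()
        if not first.startswith("#") or "source:" not in first:
            raise ValueError(f"{path}: equation file must start with a '# source:' provenance line")
        source = first.lstrip("#").strip()
        table = pd.read_csv(path, comment="#")
        return cls(table, source=source)

    @property
    def groups(self) -> list[str]:
        return sorted({g for _, g in self.table.index})

    def _row(self, patient: PatientRecord) -> pd.Series:
        try:
            return self.table.loc[(patient.sex, patient.ethnic_group)]
        except KeyError:
            raise MappingError(
                f"no coefficient row for group {patient.ethnic_group!r} "
                f"(available groups: {self.groups})"
            ) from None

    def evaluate(self, patient: PatientRecord) -> tuple[float, float, float]:
        """Return (predicted ratio, ratio LLN, predicted FEV1 in L).

        Ratios are fractions in (0, 1]; the stored coefficients are in
        percent and converted here.
        """
        row = self._row(patient)
        if not (row["age_min"] <= patient.age <= row["age_max"]):
            raise RangeError(
                f"age {patient.age} outside validated range [{row['age_min']}, {row['age_max']}]"
            )
        if not (row["height_min_cm"] <= patient.height_cm <= row["height_max_cm"]):
            raise RangeError(
                f"height {patient.height_cm} cm outside validated range "
                f"[{row['height_min_cm']}, {row['height_max_cm']}]"
            )
        pred_pct = row["ratio_intercept"] + row["ratio_age"] * patient.age
        if pd.notna(row.get("ratio_lln_intercept")):
            lln_pct = row["ratio_lln_intercept"] + row["ratio_age"] * patient.age
        elif pd.notna(row.get("ratio_see")):
            lln_pct = pred_pct - 1.645 * row["ratio_see"]
        else:
            raise ValueError("row defines neither ratio_lln_intercept nor ratio_see")
        pred_fev1 = (
            row["fev1_intercept"]
            + row["fev1_age"] * patient.age
            + row["fev1_age2"] * patient.age**2
            + row["fev1_ht2"] * patient.height_cm**2
        )
        if not (0 < lln_pct < pred_pct):
            raise ValueError(f"degenerate equation row: LLN {lln_pct} vs predicted {pred_pct}")
        if pred_fev1 <= 0:
            raise ValueError(f"non-positive predicted FEV1 {pred_fev1}")
        return float(pred_pct) / 100.0, float(lln_pct) / 100.0, float(pred_fev1)


def compute_lln(patient: PatientRecord, equations: ReferenceEquationSet) -> tuple[float, float]:
    """(LLN of the FEV1/FVC ratio, predicted FEV1 in liters) for a patient."""
    _, lln, pred_fev1 = equations.evaluate(patient)
    return lln, pred_fev1


@dataclass(frozen=True)
class ObstructionCall:
    obstructed: bool
    ratio: float
    threshold: float
    mode: str


def classify_obstruction(
    best_fev1_l: float,
    best_fvc_l: float,
    mode: str = "fixed",
    lln: Optional[float] = None,
    fixed_cut: float = 0.7,
) -> ObstructionCall:
    """Call airflow obstruction on the best-values ratio.

    fixed mode: obstruction iff ratio < fixed_cut (strictly).
    lln mode:   obstruction iff ratio < LLN (strictly); ``lln`` required.
    The ratio is carried at full precision; no rounding near the threshold.
    """
    if best_fvc_l <= 0 or best_fev1_l <= 0 or best_fev1_l > best_fvc_l:
        raise SpirometryError(f"implausible best values FEV1={best_fev1_l}, FVC={best_fvc_l}")
    ratio = best_fev1_l / best_fvc_l
    if mode == "fixed":
        threshold = fixed_cut
    elif mode == "lln":
        if lln is None:
            raise SpirometryError("lln mode requires an LLN value")
        threshold = lln
    else:
        raise SpirometryError(f"unknown obstruction mode {mode!r}")
    return ObstructionCall(obstructed=bool(ratio < threshold), ratio=float(ratio), threshold=float(threshold), mode=mode)


def interpret_session(
    session: SpirometrySession,
    patient: Optional[PatientRecord] = None,
    equations: Optional[ReferenceEquationSet] = None,
    config: Optional[EngineConfig] = None,
) -> SessionVerdict:
    """Full session pipeline: calibration → acceptability → reproducibility →
    best values → obstruction call.

    The obstruction flag is populated only for a *valid* session (calibrated
    and reproducible).  In ``lln`` mode a patient record and equation set
    are required; without them the verdict stops at validity.
    """
    cfg = config or EngineConfig()
    calibrated = check_calibration(session.last_calibration, session.session_time, cfg.calibration_max_age)
    acc = acceptable_attempts(session.attempts, cfg)
    rep = check_reproducibility(session.attempts, cfg)
    valid = calibrated and rep.reproducible
    verdict = SessionVerdict(
        session_id=session.session_id,
        calibrated=calibrated,
        acceptable_attempts=len(acc),
        reproducible=rep.reproducible,
        reason=rep.reason if rep.reason else (None if calibrated else "not_calibrated"),
        delta_fvc_l=rep.delta_fvc_l,
        delta_fev1_l=rep.delta_fev1_l,
        valid=valid,
    )
    if not valid:
        return verdict
    best_fvc, best_fev1 = select_best(acc)
    lln = None
    if cfg.obstruction_mode == "lln":
        if patient is None or equations is None:
            return verdict.model_copy(update={"best_fvc_l": best_fvc, "best_fev1_l": best_fev1,
                                              "ratio": best_fev1 / best_fvc})
        lln, _ = compute_lln(patient, equations)
    call = classify_obstruction(best_fev1, best_fvc, mode=cfg.obstruction_mode, lln=lln, fixed_cut=cfg.fixed_ratio_cut)
    return verdict.model_copy(
        update={
            "best_fvc_l": best_fvc,
            "best_fev1_l": best_fev1,
            "ratio": call.ratio,
            "threshold_mode": cfg.obstruction_mode,
            "threshold_used": call.threshold,
            "obstruction": call.obstructed,
        }
    )
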