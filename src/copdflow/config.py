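"""Engine configuration: every clinical threshold in one validated object.

All tunables ship with defaults taken from the redesigned pathway rules
(screening age cut >40 y, 2-year screening revalidation, 24 h appointment
reminder lead, 24 h calibration window, 0.15 L reproducibility threshold,
fixed ratio cut 0.7) or from conventional clinical practice where the
pathway leaves the constant open (6 s minimum forced expiratory time,
frequent-exacerbation referral at >=2/yr or >=1 hospitalization).

Durations are ISO-8601 duration strings in serialized config documents
("PT24H", "P2Y", "P7D") and ``datetime.timedelta`` in memory.
"""

from __future__ import annotations

import datetime as dt
import re
from pathlib import Path
from typing import Any, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

_DUR_RE = re.compile(
    r"^P(?:(?P<y>\d+)Y)?(?:(?P<mo>\d+)M)?(?:(?P<w>\d+)W)?(?:(?P<d>\d+)D)?"
    r"(?:T(?:(?P<h>\d+)H)?(?:(?P<mi>\d+)M)?(?:(?P<s>\d+(?:\.\d+)?)S)?)?$"
)

#: calendar approximations used when an ISO duration names years/months
DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = 30.4375


def parse_iso_duration(text: str) -> dt.timedelta:
    """Parse an ISO-8601 duration ("P2Y", "PT24H", "P7D") to a timedelta."""
    m = _DUR_RE.match(text.strip())
    if not m or text.strip() in ("P", "PT"):
        raise ValueError(f"not an ISO-8601 duration: {text!r}")
    g = {k: float(v) if v else 0.0 for k, v in m.groupdict().items()}
    days = g["y"] * DAYS_PER_YEAR + g["mo"] * DAYS_PER_MONTH + g["w"] * 7 + g["d"]
    return dt.timedelta(days=days, hours=g["h"], minutes=g["mi"], seconds=g["s"])


def format_iso_duration(td: dt.timedelta) -> str:
    """Render a timedelta as an ISO-8601 duration (days + H/M/S form)."""
    total = td.total_seconds()
    if total < 0:
        raise ValueError("negative duration")
    days, rem = divmod(total, 86400)
    hours, rem = divmod(rem, 3600)
    minutes, seconds = divmod(rem, 60)
    out = "P"
    if days:
        out += f"{int(days)}D"
    time_part = ""
    if hours:
        time_part += f"{int(hours)}H"
    if minutes:
        time_part += f"{int(minutes)}M"
    if seconds:
        s = f"{seconds:.6f}".rstrip("0").rstrip(".")
        time_part += f"{s}S"
    if time_part:
        out += "T" + time_part
    if out == "P":
        out = "PT0S"
    return out


Band = tuple[int, int, str]


def _check_bands(bands: list[Band], lo: int, hi: int, name: str, levels: tuple[str, ...]) -> None:
    """Bands must tile [lo, hi] exactly, in order, with known level labels."""
    if not bands:
        raise ValueError(f"{name}: empty band table")
    ordered = sorted(bands, key=lambda b: b[0])
    cursor = lo
    for b_lo, b_hi, label in ordered:
        if label not in levels:
            raise ValueError(f"{name}: unknown level {label!r} (allowed {levels})")
        if b_lo != cursor:
            kind = "gap" if b_lo > cursor else "overlap"
            raise ValueError(f"{name}: {kind} at score {cursor}")
        if b_hi < b_lo:
            raise ValueError(f"{name}: inverted band {b_lo}-{b_hi}")
        cursor = b_hi + 1
    if cursor != hi + 1:
        raise ValueError(f"{name}: gap at score {cursor} (table must reach {hi})")


SEVERITY_LEVELS = ("mild", "moderate", "severe", "very severe")
IMPACT_LEVELS = ("low", "moderate", "high", "very high")

_DATA_DIR = Path(__file__).parent / "data"


class EngineConfig(BaseModel):
    """All engine tunables, with pathway defaults."""

    model_config = ConfigDict(validate_assignment=True)

    # screening
    screening_age_cut: int = 40  # eligible strictly above this age
    suspicion_age_cut: int = 40  # key-indicator suspicion cut (some guidelines use 35)
    revalidation_window: dt.timedelta = dt.timedelta(days=2 * DAYS_PER_YEAR)
    # process
    reminder_lead: dt.timedelta = dt.timedelta(hours=24)
    no_show_window: dt.timedelta = dt.timedelta(days=7)
    # spirometry
    calibration_max_age: dt.timedelta = dt.timedelta(hours=24)
    reproducibility_threshold_l: float = Field(default=0.15, gt=0)
    min_fet_s: float = Field(default=6.0, gt=0)
    min_acceptable_attempts: int = Field(default=3, ge=1)
    obstruction_mode: Literal["lln", "fixed"] = "lln"
    fixed_ratio_cut: float = Field(default=0.7, gt=0, lt=1)
    # staging
    frequent_exacerbation_threshold: int = Field(default=2, ge=1)
    hospitalization_referral_threshold: int = Field(default=1, ge=1)
    index_precedence: Literal["bode", "bodex", "fev1"] = "bode"
    severity_bands_bode: list[Band] = [(0, 2, "mild"), (3, 4, "moderate"), (5, 6, "severe"), (7, 10, "very severe")]
    severity_bands_bodex: list[Band] = [(0, 2, "mild"), (3, 4, "moderate"), (5, 6, "severe"), (7, 9, "very severe")]
    severity_bands_fev1: list[Band] = [(80, 200, "mild"), (50, 79, "moderate"), (30, 49, "severe"), (0, 29, "very severe")]
    impact_bands_cat: list[Band] = [(0, 9, "low"), (10, 20, "moderate"), (21, 30, "high"), (31, 40, "very high")]
    # bundled clinical data files (each carries a provenance label inside)
    instrument_path: Path = _DATA_DIR / "instrument.yaml"
    equations_path: Path = _DATA_DIR / "reference_equations.csv"
    cutpoints_path: Path = _DATA_DIR / "index_cutpoints.csv"
    knowledge_base_path: Path = _DATA_DIR / "differential_kb.csv"
    vocabulary_path: Path = _DATA_DIR / "feature_vocabulary.csv"
    process_model_path: Path = _DATA_DIR / "process_model.yaml"

    @field_validator("revalidation_window", "reminder_lead", "no_show_window", "calibration_max_age", mode="before")
    @classmethod
    def _coerce_duration(cls, v: Any) -> Any:
        if isinstance(v, str):
            return parse_iso_duration(v)
        return v

    @model_validator(mode="after")
    def _validate_bands(self) -> "EngineConfig":
        _check_bands(self.severity_bands_bode, 0, 10, "severity_bands_bode", SEVERITY_LEVELS)
        _check_bands(self.severity_bands_bodex, 0, 9, "severity_bands_bodex", SEVERITY_LEVELS)
        _check_bands(self.impact_bands_cat, 0, 40, "impact_bands_cat", IMPACT_LEVELS)
        # FEV1 bands are descending in severity; tile 0..200 (% predicted)
        _check_bands(self.severity_bands_fev1, 0, 200, "severity_bands_fev1", SEVERITY_LEVELS)
        for f in ("revalidation_window", "reminder_lead", "no_show_window", "calibration_max_age"):
            if getattr(self, f) <= dt.timedelta(0):
                raise ValueError(f"{f} must be positive")
        return self

    def to_document(self) -> dict[str, Any]:
        """Serializable dict with ISO-8601 duration strings."""
        doc = self.model_dump(mode="json")
        for f in ("revalidation_window", "reminder_lead", "no_show_window", "calibration_max_age"):
            doc[f] = format_iso_duration(getattr(self, f))
        return doc


def validate_config(document: Optional[dict[str, Any] | str | Path]) -> EngineConfig:
    """Build an :class:`EngineConfig` from a YAML/JSON document, path or dict.

    An empty/missing document yields the full defaults.  Band-table coverage
    (no gaps, no overlaps over the index's full score range) is enforced.
    """
    if document is None:
        return EngineConfig()
    if isinstance(document, (str, Path)):
        document = yaml.safe_load(Path(document).read_text()) or {}
    if not isinstance(document, dict):
        raise ValueError("config document must be a mapping")
    doc = dict(document)
    for key in ("severity_bands_bode", "severity_bands_bodex", "severity_bands_fev1", "impact_bands_cat"):
        if key in doc:
            doc[key] = [tuple(b) for b in doc[key]]
    return EngineConfig(**doc)
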