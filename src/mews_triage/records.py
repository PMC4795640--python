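"""Row types of the ward-triage pipeline.

A :class:`VitalSigns` is one observation set of the five scored MEWS inputs
(plus diastolic pressure and SpO2, which are recorded but never scored); a
:class:`PatientRecord` adds demographics, admission context, ER-documentation
flags and the 7-day outcome.  Analysis operations accept either lists of
these dataclasses or an equivalent :class:`pandas.DataFrame`; conversion
helpers live here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Optional, Sequence

import pandas as pd

from .bands import ADMISSIBLE_RANGES, AVPU_LEVELS

__all__ = [
    "VitalSigns",
    "MEWSBreakdown",
    "PatientRecord",
    "records_to_frame",
    "frame_to_records",
    "OUTCOMES",
    "ER_FLAGS",
]

#: Allowed 7-day outcome codes.
OUTCOMES = ("died", "discharged", "on_ward", "self_discharged")

#: Vitals whose ER documentation (previous 48 h) is flagged per patient.
ER_FLAGS = ("hr", "bp", "rr", "spo2", "gcs")

SOURCES = ("emergency", "government_unit", "private_hospital")


@dataclass(frozen=True)
class VitalSigns:
    """One set of bedside observations.

    sbp/dbp in mmHg, pulse in beats/min, rr in breaths/min, temp in degrees
    Celsius (axillary), avpu one of ``A``/``V``/``P``/``U``.  ``dbp`` and
    ``spo2`` are optional passthrough fields and never enter the score.
    """

    sbp: float
    pulse: float
    rr: float
    temp: float
    avpu: str
    dbp: Optional[float] = None
    spo2: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("sbp", "pulse", "rr", "temp"):
            value = getattr(self, name)
            if value is None or not math.isfinite(float(value)):
                raise ValueError(f"vital sign {name} is missing or non-finite")
            lo, hi = ADMISSIBLE_RANGES[name]
            if not (lo <= float(value) <= hi):
                raise ValueError(f"{name} = {value} outside admissible [{lo}, {hi}]")
        if self.avpu not in AVPU_LEVELS:
            raise ValueError(f"avpu must be one of {AVPU_LEVELS}, got {self.avpu!r}")
        if self.spo2 is not None and not (0 <= float(self.spo2) <= 100):
            raise ValueError(f"spo2 = {self.spo2} outside [0, 100]")


@dataclass(frozen=True)
class MEWSBreakdown:
    """Per-parameter subscores and their total for one patient."""

    sub_sbp: int
    sub_pulse: int
    sub_rr: int
    sub_temp: int
    sub_avpu: int
    total: int

    def __post_init__(self) -> None:
        parts = (self.sub_sbp, self.sub_pulse, self.sub_rr, self.sub_temp, self.sub_avpu)
        if self.total != sum(parts):
            raise ValueError("total must equal the sum of the five subscores")
        if not (0 <= self.total <= 14):
            raise ValueError("total out of range 0-14")


@dataclass(frozen=True)
class PatientRecord:
    """Demographics, admission context, vitals and 7-day outcome."""

    id: str
    age: float
    sex: str  # male / female
    service: str  # medical / surgical
    surgical_phase: str  # preoperative / postoperative / not_applicable
    trauma: bool
    hiv: str  # positive / negative / unknown
    source: str  # emergency / government_unit / private_hospital
    attendant: bool
    days_pre_enrollment: float
    vitals: VitalSigns
    er_documented: frozenset = frozenset()
    outcome7: str = "on_ward"

    def __post_init__(self) -> None:
        if self.age < 18:
            raise ValueError("age must be >= 18 (adult wards only)")
        if self.days_pre_enrollment < 0:
            raise ValueError("days_pre_enrollment must be >= 0")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")
        if self.service not in ("medical", "surgical"):
            raise ValueError(f"service must be medical/surgical, got {self.service!r}")
        if (self.surgical_phase != "not_applicable") != (self.service == "surgical"):
            raise ValueError(
                "surgical_phase must be pre-/postoperative iff service is surgical"
            )
        if self.hiv not in ("positive", "negative", "unknown"):
            raise ValueError(f"hiv must be positive/negative/unknown, got {self.hiv!r}")
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")
        if self.outcome7 not in OUTCOMES:
            raise ValueError(f"outcome7 must be one of {OUTCOMES}, got {self.outcome7!r}")
        if not set(self.er_documented) <= set(ER_FLAGS):
            raise ValueError(f"er_documented flags must be among {ER_FLAGS}")

    def to_row(self) -> dict:
        v = self.vitals
        row = {
            "id": self.id,
            "age": self.age,
            "sex": self.sex,
            "service": self.service,
            "surgical_phase": self.surgical_phase,
            "trauma": self.trauma,
            "hiv": self.hiv,
            "source": self.source,
            "attendant": self.attendant,
            "days_pre_enrollment": self.days_pre_enrollment,
            "sbp": v.sbp,
            "dbp": v.dbp,
            "pulse": v.pulse,
            "rr": v.rr,
            "temp": v.temp,
            "avpu": v.avpu,
            "spo2": v.spo2,
            "outcome7": self.outcome7,
        }
        for flag in ER_FLAGS:
            row[f"er_{flag}_doc"] = flag in self.er_documented
        return row


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Materialize records as the standard tabular layout (one row/patient)."""
    return pd.DataFrame([r.to_row() for r in records])


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    """Inverse of :func:`records_to_frame`; validates every row."""
    out = []
    for _, row in frame.iterrows():
        vitals = VitalSigns(
            sbp=row["sbp"],
            pulse=row["pulse"],
            rr=row["rr"],
            temp=row["temp"],
            avpu=row["avpu"],
            dbp=_opt(row.get("dbp")),
            spo2=_opt(row.get("spo2")),
        )
        flags = frozenset(f for f in ER_FLAGS if bool(row.get(f"er_{f}_doc", False)))
        out.append(
            PatientRecord(
                id=str(row["id"]),
                age=float(row["age"]),
                sex=row["sex"],
                service=row["service"],
                surgical_phase=row.get("surgical_phase", "not_applicable"),
                trauma=bool(row["trauma"]),
                hiv=row["hiv"],
                source=row["source"],
                attendant=bool(row["attendant"]),
                days_pre_enrollment=float(row["days_pre_enrollment"]),
                vitals=vitals,
                er_documented=flags,
                outcome7=row["outcome7"],
            )
        )
    return out


def _opt(value):
    if value is None:
        return None
    try:
        if pd.isna(value):
            return None
    except (TypeError, ValueError):
        pass
    return float(value)


def as_frame(data) -> pd.DataFrame:
    """Coerce a DataFrame or a sequence of PatientRecord to a DataFrame."""
    if isinstance(data, pd.DataFrame):
        return data
    return records_to_frame(list(data))
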