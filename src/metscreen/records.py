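"""Participant-level data containers and validation.

A :class:`ParticipantRecord` holds one subject's raw measurements in the
units the rest of the package expects:

* lengths/circumferences in cm, weight in kg
* blood pressure in mmHg
* fasting blood glucose in mg/dL
* triglycerides and HDL-cholesterol in mmol/L (no silent conversion)

Medication flags are carried separately because they can satisfy a
metabolic-syndrome component irrespective of the measured value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

__all__ = ["ParticipantRecord", "DomainError", "SEXES"]

SEXES = ("male", "female")

#: fields that must be strictly positive
_POSITIVE = ("height", "weight", "wc", "nc", "muac", "hdl", "sbp", "dbp")
#: fields that must be non-negative
_NONNEG = ("tg", "fbg", "age")


class DomainError(ValueError):
    """A measurement is outside its mathematical domain.

    Carries the offending field name in :attr:`field`.
    """

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass(frozen=True)
class ParticipantRecord:
    """One subject's raw measurements with fixed units.

    Parameters
    ----------
    id : str
        Opaque participant identifier.
    sex : {"male", "female"}
    age : float
        Years. Values below 25 trigger a warning (a study-eligibility
        criterion, not a mathematical requirement), never an error.
    height, wc, nc, muac : float
        Centimetres (height, waist, neck, mid-upper-arm circumference).
    weight : float
        Kilograms.
    sbp, dbp : float
        Systolic / diastolic blood pressure, mmHg.
    fbg : float
        Fasting blood glucose, mg/dL.
    tg, hdl : float
        Triglycerides / HDL-cholesterol, mmol/L.
    on_bp_meds, on_lipid_meds, on_glucose_meds : bool
        Prescribed antihypertensive / lipid-lowering / glucose-lowering
        medication.
    """

    id: str
    sex: str
    age: float
    height: float
    weight: float
    wc: float
    nc: float
    muac: float
    sbp: float
    dbp: float
    fbg: float
    tg: float
    hdl: float
    on_bp_meds: bool = False
    on_lipid_meds: bool = False
    on_glucose_meds: bool = False

    def __post_init__(self):
        if self.sex not in SEXES:
            raise DomainError("sex", f"must be one of {SEXES}, got {self.sex!r}")
        for name in _POSITIVE:
            v = getattr(self, name)
            if not v > 0:
                raise DomainError(name, f"must be > 0, got {v!r}")
        for name in _NONNEG:
            v = getattr(self, name)
            if not v >= 0:
                raise DomainError(name, f"must be >= 0, got {v!r}")
        if not self.sbp > self.dbp:
            raise DomainError("sbp", f"systolic ({self.sbp}) must exceed diastolic ({self.dbp})")
        if self.age < 25:
            warnings.warn(
                f"participant {self.id!r}: age {self.age} below the usual "
                "adult-screening floor of 25 years",
                stacklevel=2,
            )

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]
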