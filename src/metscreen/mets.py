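"""Metabolic-syndrome component classification (harmonized 3-of-5 rule).

A subject is MetS-positive when at least three of the five components hold:

* elevated waist circumference: WC >= 90 cm (men) / 80 cm (women)
  (ethnicity-specific Asian thresholds)
* elevated blood pressure: SBP >= 130 mmHg OR DBP >= 85 mmHg, or on
  antihypertensive medication
* reduced HDL-c: < 1.03 mmol/L (men) / < 1.29 mmol/L (women), or on
  lipid-lowering medication
* elevated triglycerides: >= 1.7 mmol/L, or on lipid-lowering medication
* elevated fasting glucose: >= 100 mg/dL, or on glucose-lowering medication

Boundary comparisons are inclusive exactly as written (>= for elevations,
strict < for the HDL deficit). A strict-IDF variant (central obesity
mandatory plus any two of the remaining four) is available behind the
``strict_idf`` flag for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import ParticipantRecord
from .stats import PropCI, proportion_ci

__all__ = [
    "ThresholdSet",
    "MetSResult",
    "COMPONENT_NAMES",
    "classify_components",
    "classify_components_df",
    "mets_prevalence",
]

COMPONENT_NAMES = [
    "elevated_wc",
    "elevated_bp",
    "reduced_hdl",
    "elevated_tg",
    "elevated_fbg",
]


@dataclass(frozen=True)
class ThresholdSet:
    """Component cut-points; defaults are the harmonized/Asian values."""

    wc_male: float = 90.0  # cm
    wc_female: float = 80.0  # cm
    sbp: float = 130.0  # mmHg
    dbp: float = 85.0  # mmHg
    hdl_male: float = 1.03  # mmol/L
    hdl_female: float = 1.29  # mmol/L
    tg: float = 1.7  # mmol/L
    fbg: float = 100.0  # mg/dL

    def __post_init__(self):
        vals = asdict(self)
        for name, v in vals.items():
            if not v > 0:
                raise ValueError(f"threshold {name} must be positive, got {v}")
        if not self.wc_male > self.wc_female:
            raise ValueError("wc_male must exceed wc_female")
        if not self.hdl_male < self.hdl_female:
            raise ValueError("hdl_male must be below hdl_female")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdSet":
        return cls(**d)


DEFAULT_THRESHOLDS = ThresholdSet()


@dataclass(frozen=True)
class MetSResult:
    """Five component flags plus the overall call for one subject."""

    elevated_wc: bool
    elevated_bp: bool
    reduced_hdl: bool
    elevated_tg: bool
    elevated_fbg: bool
    n_components: int
    mets: bool

    def __post_init__(self):
        flags = [getattr(self, c) for c in COMPONENT_NAMES]
        if self.n_components != sum(flags):
            raise ValueError("n_components inconsistent with flags")


def classify_components(
    record: ParticipantRecord,
    thresholds: ThresholdSet = DEFAULT_THRESHOLDS,
    strict_idf: bool = False,
) -> MetSResult:
    """Classify one subject's five components and overall MetS status.

    Pure and deterministic. With ``strict_idf=True`` the overall call
    requires elevated WC plus any two other components instead of any
    three of five.
    """
    male = record.sex == "male"
    wc_thr = thresholds.wc_male if male else thresholds.wc_female
    hdl_thr = thresholds.hdl_male if male else thresholds.hdl_female

    elevated_wc = record.wc >= wc_thr
    elevated_bp = (
        record.sbp >= thresholds.sbp
        or record.dbp >= thresholds.dbp
        or record.on_bp_meds
    )
    reduced_hdl = record.hdl < hdl_thr or record.on_lipid_meds
    elevated_tg = record.tg >= thresholds.tg or record.on_lipid_meds
    elevated_fbg = record.fbg >= thresholds.fbg or record.on_glucose_meds

    flags = (elevated_wc, elevated_bp, reduced_hdl, elevated_tg, elevated_fbg)
    n = sum(flags)
    if strict_idf:
        mets = elevated_wc and (n - 1) >= 2
    else:
        mets = n >= 3
    return MetSResult(*[bool(f) for f in flags], n_components=int(n), mets=bool(mets))


def classify_components_df(
    df: pd.DataFrame,
    thresholds: ThresholdSet = DEFAULT_THRESHOLDS,
    strict_idf: bool = False,
) -> pd.DataFrame:
    """Vectorised classification for a cohort table.

    Expects the standard cohort columns (``sex, wc, sbp, dbp, hdl, tg,
    fbg`` and the three medication flags; missing flag columns are treated
    as all-False). Returns a DataFrame with the five boolean component
    columns plus ``n_components`` and ``mets``.
    """
    male = df["sex"].to_numpy() == "male"

    def flag(name):
        if name in df.columns:
            return df[name].fillna(False).to_numpy(bool)
        return np.zeros(len(df), bool)

    wc_thr = np.where(male, thresholds.wc_male, thresholds.wc_female)
    hdl_thr = np.where(male, thresholds.hdl_male, thresholds.hdl_female)

    elevated_wc = df["wc"].to_numpy(float) >= wc_thr
    elevated_bp = (
        (df["sbp"].to_numpy(float) >= thresholds.sbp)
        | (df["dbp"].to_numpy(float) >= thresholds.dbp)
        | flag("on_bp_meds")
    )
    lipid = flag("on_lipid_meds")
    reduced_hdl = (df["hdl"].to_numpy(float) < hdl_thr) | lipid
    elevated_tg = (df["tg"].to_numpy(float) >= thresholds.tg) | lipid
    elevated_fbg = (df["fbg"].to_numpy(float) >= thresholds.fbg) | flag(
        "on_glucose_meds"
    )

    out = pd.DataFrame(
        {
            "elevated_wc": elevated_wc,
            "elevated_bp": elevated_bp,
            "reduced_hdl": reduced_hdl,
            "elevated_tg": elevated_tg,
            "elevated_fbg": elevated_fbg,
        },
        index=df.index,
    )
    n = out.to_numpy(int).sum(axis=1)
    out["n_components"] = n
    if strict_idf:
        out["mets"] = elevated_wc & ((n - elevated_wc.astype(int)) >= 2)
    else:
        out["mets"] = n >= 3
    return out


def mets_prevalence(
    results: Iterable[MetSResult] | Sequence[bool] | np.ndarray | pd.Series,
    method: str = "wilson",
) -> PropCI:
    """Fraction of MetS-positive subjects with a 95% CI.

    Accepts either an iterable of :class:`MetSResult` or a boolean
    array/Series of overall calls.
    """
    if isinstance(results, (np.ndarray, pd.Series)):
        flags = np.asarray(results, bool)
    else:
        items = list(results)
        if items and isinstance(items[0], MetSResult):
            flags = np.array([r.mets for r in items], bool)
        else:
            flags = np.asarray(items, bool)
    if flags.size == 0:
        raise ValueError("empty collection")
    return proportion_ci(int(flags.sum()), int(flags.size), method=method)
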