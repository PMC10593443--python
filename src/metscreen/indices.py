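"""The nine anthropometric indices used for metabolic-syndrome screening.

Each formula takes inputs in the units stated in its signature; all unit
conversions (cm -> m where an index is defined in metres) are centralised
in :func:`compute_index_panel` / :func:`compute_indices_df` and applied
exactly once.

Index conventions
-----------------
bmi
    weight / height**2, kg/m^2.
whtr
    waist-to-height ratio, both in cm (dimensionless).
conicity
    wc_m / (k * sqrt(weight/height_m)), the waist normalised by the
    circumference of a cylinder of the subject's mass and height. The
    standard constant is k = 0.109; it is exposed as a parameter because
    some sources print 0.09, which inflates the index by ~21% and is
    inconsistent with typical population means (~1.2-1.35).
rpi
    reciprocal ponderal index, height_cm / weight**(1/3) (units
    cm.kg^(-1/3); population means ~37-41).
bsi
    a body shape index (ABSI convention), wc_m / (bmi**(2/3) * sqrt(height_m)).
vai
    visceral adiposity index, the sex-specific composite of WC (cm), BMI,
    TG and HDL (both mmol/L):

        male:   [wc / (39.68 + 1.88*bmi)] * (tg/1.03) * (1.31/hdl)
        female: [wc / (36.58 + 1.89*bmi)] * (tg/0.81) * (1.52/hdl)

    The "+" in the linear denominator is the standard formulation; a "-"
    there would make the denominator negative for any adult BMI.

``nc``, ``muac`` and ``wc`` complete the panel as pass-through measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import DomainError, ParticipantRecord

__all__ = [
    "IndexPanel",
    "INDEX_NAMES",
    "CONICITY_K_DEFAULT",
    "VAI_COEFFS",
    "compute_bmi",
    "compute_whtr",
    "compute_conicity",
    "compute_rpi",
    "compute_bsi",
    "compute_vai",
    "compute_index_panel",
    "compute_indices_df",
]

#: canonical column order of the nine-index panel
INDEX_NAMES = ["bmi", "nc", "muac", "wc", "whtr", "conicity", "rpi", "bsi", "vai"]

CONICITY_K_DEFAULT = 0.109

#: sex -> (intercept, bmi slope, tg divisor, hdl numerator)
VAI_COEFFS = {
    "male": (39.68, 1.88, 1.03, 1.31),
    "female": (36.58, 1.89, 0.81, 1.52),
}


def _require_positive(**named):
    for name, value in named.items():
        arr = np.asarray(value, dtype=float)
        if not np.all(arr > 0):
            raise DomainError(name, "must be > 0")


def compute_bmi(weight: float, height_m: float) -> float:
    """Body mass index, kg/m^2. ``height_m`` is in metres."""
    _require_positive(weight=weight, height=height_m)
    return weight / height_m**2


def compute_whtr(wc: float, height: float) -> float:
    """Waist-to-height ratio; both arguments in cm (any common unit)."""
    _require_positive(wc=wc, height=height)
    return wc / height


def compute_conicity(
    wc_m: float, weight: float, height_m: float, k: float = CONICITY_K_DEFAULT
) -> float:
    """Conicity index; waist and height in metres, weight in kg."""
    _require_positive(wc=wc_m, weight=weight, height=height_m, k=k)
    return wc_m / (k * np.sqrt(weight / height_m))


def compute_rpi(height: float, weight: float) -> float:
    """Reciprocal ponderal index, height (cm) / weight(kg)**(1/3)."""
    _require_positive(height=height, weight=weight)
    return height / np.cbrt(weight)


def compute_bsi(wc_m: float, bmi: float, height_m: float) -> float:
    """A body shape index (ABSI); waist and height in metres."""
    _require_positive(wc=wc_m, bmi=bmi, height=height_m)
    return wc_m / (bmi ** (2.0 / 3.0) * np.sqrt(height_m))


def compute_vai(sex, wc: float, bmi: float, tg: float, hdl: float) -> float:
    """Visceral adiposity index; wc in cm, tg/hdl in mmol/L.

    ``sex`` may be a scalar ``"male"``/``"female"`` or an array of those
    strings (vectorised use).
    """
    _require_positive(wc=wc, bmi=bmi, tg=tg, hdl=hdl)
    if np.isscalar(sex) or isinstance(sex, str):
        try:
            a, b, tg0, hdl0 = VAI_COEFFS[sex]
        except KeyError:
            raise DomainError("sex", f"unknown sex {sex!r}") from None
        return (wc / (a + b * bmi)) * (tg / tg0) * (hdl0 / hdl)
    sex = np.asarray(sex)
    unknown = ~np.isin(sex, list(VAI_COEFFS))
    if unknown.any():
        raise DomainError("sex", f"unknown sex values {np.unique(sex[unknown])!r}")
    male = sex == "male"
    a = np.where(male, 39.68, 36.58)
    b = np.where(male, 1.88, 1.89)
    tg0 = np.where(male, 1.03, 0.81)
    hdl0 = np.where(male, 1.31, 1.52)
    return (np.asarray(wc, float) / (a + b * np.asarray(bmi, float))) * (
        np.asarray(tg, float) / tg0
    ) * (hdl0 / np.asarray(hdl, float))


@dataclass(frozen=True)
class IndexPanel:
    """The nine derived indices for one subject (units as in module docs)."""

    bmi: float
    nc: float
    muac: float
    wc: float
    whtr: float
    conicity: float
    rpi: float
    bsi: float
    vai: float


def compute_index_panel(
    record: ParticipantRecord, conicity_k: float = CONICITY_K_DEFAULT
) -> IndexPanel:
    """Compute the full nine-index panel from a raw record.

    cm -> m conversions for BMI, conicity and BSI happen here, exactly once.
    Domain errors from individual formulas propagate with the offending
    field named.
    """
    height_m = record.height / 100.0
    wc_m = record.wc / 100.0
    bmi = compute_bmi(record.weight, height_m)
    return IndexPanel(
        bmi=bmi,
        nc=record.nc,
        muac=record.muac,
        wc=record.wc,
        whtr=compute_whtr(record.wc, record.height),
        conicity=compute_conicity(wc_m, record.weight, height_m, k=conicity_k),
        rpi=compute_rpi(record.height, record.weight),
        bsi=compute_bsi(wc_m, bmi, height_m),
        vai=compute_vai(record.sex, record.wc, bmi, record.tg, record.hdl),
    )


def compute_indices_df(
    df: pd.DataFrame, conicity_k: float = CONICITY_K_DEFAULT
) -> pd.DataFrame:
    """Vectorised panel computation for a cohort table.

    ``df`` must carry columns ``sex, height, weight, wc, nc, muac, tg, hdl``
    in the package's standard units. Returns a DataFrame with the nine
    index columns (same row index as ``df``). Rows with missing inputs
    yield NaN in the affected indices rather than raising.
    """
    height_m = df["height"].to_numpy(float) / 100.0
    wc_cm = df["wc"].to_numpy(float)
    wc_m = wc_cm / 100.0
    weight = df["weight"].to_numpy(float)
    tg = df["tg"].to_numpy(float)
    hdl = df["hdl"].to_numpy(float)
    sex = df["sex"].to_numpy()

    with np.errstate(invalid="ignore", divide="ignore"):
        bmi = weight / height_m**2
        male = sex == "male"
        a = np.where(male, 39.68, 36.58)
        b = np.where(male, 1.88, 1.89)
        tg0 = np.where(male, 1.03, 0.81)
        hdl0 = np.where(male, 1.31, 1.52)
        out = pd.DataFrame(
            {
                "bmi": bmi,
                "nc": df["nc"].to_numpy(float),
                "muac": df["muac"].to_numpy(float),
                "wc": wc_cm,
                "whtr": wc_cm / (height_m * 100.0),
                "conicity": wc_m / (conicity_k * np.sqrt(weight / height_m)),
                "rpi": (height_m * 100.0) / np.cbrt(weight),
                "bsi": wc_m / (bmi ** (2.0 / 3.0) * np.sqrt(height_m)),
                "vai": (wc_cm / (a + b * bmi)) * (tg / tg0) * (hdl0 / hdl),
            },
            index=df.index,
        )
    return out
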