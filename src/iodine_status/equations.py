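"""Spot-to-24-h urinary biomarker prediction equations and unit plumbing.

Assessing iodine status from a single spot urine sample requires
extrapolating a concentration (µg/L) to a daily excretion (µg/day).  The
standard device is predicted 24-h urinary creatinine excretion (PrCr,
mg/day): creatinine concentration tracks the dilution state of the urine,
so the iodine-to-creatinine ratio of the spot sample multiplied by the
person's expected daily creatinine output yields a predicted 24-h urinary
iodine excretion (PrUIE, µg/day).

Three published anthropometry-based PrCr equations are implemented:

* **Tanaka** — a single sex-independent linear equation in age, weight and
  height, developed in Japanese adults.
* **Kawasaki** — sex-specific linear equations in age, weight and height.
* **Mage** — sex-specific multiplicative equations in age, lean-mass proxy
  ``weight^1.5 * height^0.5``, with a race/BMI correction term controlled
  by an indicator ``A`` (black/African ancestry = 1, otherwise 0).  When
  the indicator is missing the prediction is undefined and is propagated
  as missing rather than assumed zero.

Alongside the equations live the iodine-specific conversions: measured
24-h urinary iodine excretion (mUIE) from volume and pool concentration,
excretion-to-intake conversion through the 92% absorption fraction, the
IOM weight-based intake equation, the creatinine mg/mmol unit converters,
and the completeness screen that rejects under-collected 24-h urine
(volume ≤ 300 mL, or daily creatinine ≤ 4 mmol for women / ≤ 6 mmol for
men).

All low-level functions are plain arithmetic on numpy-compatible inputs
(scalars or arrays); the dataclass wrappers add validation and the
missing-data conventions described above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "Sex",
    "Equation",
    "InputError",
    "ImplausibleInputError",
    "Participant",
    "SpotSample",
    "Urine24h",
    "PredictedCreatinine",
    "tanaka_creatinine",
    "kawasaki_creatinine",
    "mage_creatinine",
    "predicted_uie",
    "predict_creatinine",
    "predict_creatinine_tanaka",
    "predict_creatinine_kawasaki",
    "predict_creatinine_mage",
    "predict_uie",
    "measured_uie",
    "intake_from_excretion",
    "iom_intake",
    "is_complete_collection",
    "creatinine_mg_to_mmol",
    "creatinine_mmol_to_mg",
    "CREATININE_MG_PER_MMOL",
    "IODINE_BIOAVAILABILITY",
    "IOM_URINE_OUTPUT_L_PER_H_PER_KG",
    "INCOMPLETE_VOLUME_ML",
    "INCOMPLETE_CREATININE_MMOL",
]

#: Molar mass of creatinine, mg per mmol.
CREATININE_MG_PER_MMOL = 113.12

#: Fraction of dietary iodine absorbed; divides excretion to estimate intake.
IODINE_BIOAVAILABILITY = 0.92

#: Urine output rate used by the IOM weight-based intake equation.
IOM_URINE_OUTPUT_L_PER_H_PER_KG = 0.0009

#: 24-h collections at or below this volume are treated as incomplete.
INCOMPLETE_VOLUME_ML = 300.0

#: Sex-specific daily creatinine floors (mmol/day); at or below → incomplete.
INCOMPLETE_CREATININE_MMOL = {"female": 4.0, "male": 6.0}


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Equation(str, Enum):
    TANAKA = "tanaka"
    KAWASAKI = "kawasaki"
    MAGE = "mage"


class InputError(ValueError):
    """Missing or out-of-domain input to a prediction equation."""


class ImplausibleInputError(ValueError):
    """Inputs inside the formal domain but yielding a non-physiological result.

    Raised instead of silently clamping, because a clamped (e.g. zero or
    negative) predicted creatinine would bias every downstream PrUIE.
    """


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


def _coerce_sex(sex) -> Sex:
    if sex is None:
        raise InputError("sex is required")
    if isinstance(sex, Sex):
        return sex
    try:
        return Sex(str(sex).strip().lower())
    except ValueError as exc:
        raise InputError(f"unrecognised sex: {sex!r}") from exc


@dataclass
class Participant:
    """Demographics and anthropometry driving the prediction equations.

    ``bmi`` is recomputed from weight/height when absent; a supplied BMI is
    kept but must agree with weight/(height/100)^2 within 0.5 kg/m².
    ``ethnicity_black`` is the Mage race indicator ``A`` and may be missing
    (``None``), in which case the Mage prediction is itself missing.
    """

    id: str
    sex: Sex
    age: float
    weight: float
    height: float
    bmi: Optional[float] = None
    ethnicity_black: Optional[int] = None

    def __post_init__(self) -> None:
        self.sex = _coerce_sex(self.sex)
        for name in ("age", "weight", "height"):
            value = getattr(self, name)
            if value is None or not math.isfinite(value) or value <= 0:
                raise InputError(f"{name} must be a positive number, got {value!r}")
        derived = self.weight / (self.height / 100.0) ** 2
        if self.bmi is None:
            self.bmi = derived
        elif abs(self.bmi - derived) > 0.5:
            raise InputError(
                f"supplied bmi {self.bmi:.2f} inconsistent with "
                f"weight/height ({derived:.2f} kg/m²)"
            )
        if self.ethnicity_black is not None and self.ethnicity_black not in (0, 1):
            raise InputError("ethnicity_black must be 0, 1 or None")


@dataclass
class SpotSample:
    """A casual (spot) urine sample: iodine µg/L and creatinine mg/dL."""

    uic: float
    ucr_mg_dl: float

    def __post_init__(self) -> None:
        if self.uic is None or self.uic < 0:
            raise InputError("spot UIC must be >= 0")
        if self.ucr_mg_dl is None or self.ucr_mg_dl <= 0:
            raise InputError("spot creatinine must be > 0 (it is a denominator)")


@dataclass
class Urine24h:
    """A 24-h collection: volume mL, pool iodine µg/L, creatinine mmol/day."""

    volume_ml: float
    iodine_ug_l: float
    creatinine_mmol_day: float

    def __post_init__(self) -> None:
        for name in ("volume_ml", "iodine_ug_l", "creatinine_mmol_day"):
            value = getattr(self, name)
            if value is None or value < 0:
                raise InputError(f"{name} must be >= 0, got {value!r}")


@dataclass
class PredictedCreatinine:
    """A PrCr value (mg/day) labelled with the equation that produced it."""

    equation: Equation
    prcr_mg_day: float


# ---------------------------------------------------------------------------
# low-level vectorisable arithmetic
# ---------------------------------------------------------------------------


def tanaka_creatinine(age, weight, height):
    """Tanaka PrCr, mg/day: sex-independent linear equation.

    ``-2.04*age + 14.89*weight + 16.14*height - 2244.45`` with age in
    years, weight in kg, height in cm.
    """
    return -2.04 * age + 14.89 * weight + 16.14 * height - 2244.45


def kawasaki_creatinine(age, weight, height, female):
    """Kawasaki PrCr, mg/day: sex-specific linear equations.

    Men:   ``12.63*age + 15.12*weight + 7.39*height - 79.9``
    Women: ``-4.72*age + 8.58*weight + 5.09*height - 74.5``
    """
    men = 12.63 * age + 15.12 * weight + 7.39 * height - 79.9
    women = -4.72 * age + 8.58 * weight + 5.09 * height - 74.5
    return np.where(female, women, men)


def mage_creatinine(age, weight, height, bmi, black, female):
    """Mage PrCr, mg/day: multiplicative lean-mass equation with race/BMI term.

    ``k * (140 - age) * weight^1.5 * height^0.5 * (1 + 0.18*A*(b1 - b2*BMI))``
    with (k, b1, b2) = (0.00179, 1.366, 0.0159) for men and
    (0.00163, 1.429, 0.0198) for women.  With ``A = 0`` the bracket
    collapses to 1.  ``black`` may contain NaN, which propagates.
    """
    k = np.where(female, 0.00163, 0.00179)
    b1 = np.where(female, 1.429, 1.366)
    b2 = np.where(female, 0.0198, 0.0159)
    race = 1.0 + 0.18 * np.asarray(black, dtype=float) * (b1 - b2 * bmi)
    return k * (140.0 - age) * weight**1.5 * height**0.5 * race


def predicted_uie(uic, ucr, prcr_mg_day, ucr_unit: str = "mg/dL"):
    """PrUIE µg/day from a spot iodine/creatinine ratio and a PrCr.

    The ratio is formed in µg iodine per mg creatinine, so the spot
    creatinine concentration is first brought to mg/L (1 mg/dL = 10 mg/L);
    multiplying by PrCr in mg/day cancels the mg to leave µg/day.
    """
    if ucr_unit == "mg/dL":
        ucr_mg_l = np.asarray(ucr, dtype=float) * 10.0
    elif ucr_unit == "mg/L":
        ucr_mg_l = np.asarray(ucr, dtype=float)
    else:
        raise InputError(f"unknown spot creatinine unit {ucr_unit!r}")
    return uic / ucr_mg_l * prcr_mg_day


# ---------------------------------------------------------------------------
# participant-level operations
# ---------------------------------------------------------------------------


def predict_creatinine_tanaka(p: Participant) -> PredictedCreatinine:
    """Predict 24-h creatinine excretion with the Tanaka equation."""
    value = float(tanaka_creatinine(p.age, p.weight, p.height))
    if value <= 0:
        raise ImplausibleInputError(
            f"Tanaka PrCr {value:.1f} mg/day <= 0 for participant {p.id!r}"
        )
    return PredictedCreatinine(Equation.TANAKA, value)


def predict_creatinine_kawasaki(p: Participant) -> PredictedCreatinine:
    """Predict 24-h creatinine excretion with the sex-specific Kawasaki equation."""
    value = float(
        kawasaki_creatinine(p.age, p.weight, p.height, p.sex is Sex.FEMALE)
    )
    if value <= 0:
        raise ImplausibleInputError(
            f"Kawasaki PrCr {value:.1f} mg/day <= 0 for participant {p.id!r}"
        )
    return PredictedCreatinine(Equation.KAWASAKI, value)


def predict_creatinine_mage(p: Participant) -> Optional[PredictedCreatinine]:
    """Predict 24-h creatinine excretion with the Mage equation.

    Returns ``None`` when the race indicator is missing — the prediction
    cannot be formed and the participant drops out of Mage-based analyses
    (list-wise, for that equation only).  Ages of 140 or more are outside
    the equation's domain (the ``140 - age`` factor changes sign).
    """
    if p.age >= 140:
        raise InputError("Mage equation domain requires age < 140")
    if p.ethnicity_black is None:
        return None
    value = float(
        mage_creatinine(
            p.age, p.weight, p.height, p.bmi, p.ethnicity_black, p.sex is Sex.FEMALE
        )
    )
    if value <= 0:
        raise ImplausibleInputError(
            f"Mage PrCr {value:.1f} mg/day <= 0 for participant {p.id!r}"
        )
    return PredictedCreatinine(Equation.MAGE, value)


_PREDICTORS = {
    Equation.TANAKA: predict_creatinine_tanaka,
    Equation.KAWASAKI: predict_creatinine_kawasaki,
    Equation.MAGE: predict_creatinine_mage,
}


def predict_creatinine(p: Participant, equation) -> Optional[PredictedCreatinine]:
    """Dispatch to one of the three PrCr equations by name."""
    return _PREDICTORS[Equation(equation)](p)


def predict_uie(spot: SpotSample, prcr: PredictedCreatinine) -> float:
    """Predicted 24-h urinary iodine excretion, µg/day."""
    if spot.ucr_mg_dl <= 0:
        raise InputError("spot creatinine must be > 0")
    return float(predicted_uie(spot.uic, spot.ucr_mg_dl, prcr.prcr_mg_day))


def measured_uie(u: Urine24h) -> float:
    """Measured 24-h urinary iodine excretion: volume (L) × pool iodine (µg/L)."""
    return u.volume_ml / 1000.0 * u.iodine_ug_l


def intake_from_excretion(uie, bioavailability: float = IODINE_BIOAVAILABILITY):
    """Estimated daily iodine intake: excretion divided by the absorbed fraction."""
    if np.any(np.asarray(uie) < 0):
        raise InputError("excretion must be >= 0")
    return uie / bioavailability


def iom_intake(uic, weight, bioavailability: float = IODINE_BIOAVAILABILITY):
    """IOM weight-based daily iodine intake estimate, µg/day.

    ``(UIC/0.92) × (0.0009 L/h/kg × 24 h × weight kg)`` — the bracket is the
    expected daily urine volume in litres, scaled from a child-derived
    output rate.
    """
    if np.any(np.asarray(weight) <= 0):
        raise InputError("weight must be > 0")
    if np.any(np.asarray(uic) < 0):
        raise InputError("UIC must be >= 0")
    return (uic / bioavailability) * (IOM_URINE_OUTPUT_L_PER_H_PER_KG * 24.0 * weight)


def is_complete_collection(
    u: Urine24h,
    sex,
    volume_threshold_ml: float = INCOMPLETE_VOLUME_ML,
    creatinine_thresholds_mmol=None,
) -> bool:
    """Screen a 24-h collection for completeness.

    Incomplete iff volume ≤ 300 mL, or daily creatinine ≤ 4 mmol (women) /
    ≤ 6 mmol (men).  Thresholds are inclusive exclusions.
    """
    sex = _coerce_sex(sex)
    thresholds = creatinine_thresholds_mmol or INCOMPLETE_CREATININE_MMOL
    if u.volume_ml <= volume_threshold_ml:
        return False
    if u.creatinine_mmol_day <= thresholds[sex.value]:
        return False
    return True


def creatinine_mg_to_mmol(x):
    """Convert creatinine mg/day to mmol/day (molar mass 113.12 mg/mmol)."""
    if np.any(np.asarray(x) < 0):
        raise InputError("creatinine must be >= 0")
    return x / CREATININE_MG_PER_MMOL


def creatinine_mmol_to_mg(x):
    """Convert creatinine mmol/day to mg/day."""
    if np.any(np.asarray(x) < 0):
        raise InputError("creatinine must be >= 0")
    return x * CREATININE_MG_PER_MMOL
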