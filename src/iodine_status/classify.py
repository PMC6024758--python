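"""Iodine adequacy classification and 2×2 agreement statistics.

Individuals are classified against the adult Estimated Average Requirement
(EAR) for iodine, 95 µg/day: an estimated usual intake strictly below the
EAR counts as inadequate (the EAR cut-point method estimates the population
prevalence of inadequacy as the fraction below this cut-off).  Populations
are additionally classified by the median spot urinary iodine concentration
(MUIC): a median below 100 µg/L flags population-level deficiency in
non-pregnant adults, and the fractions below 100 and 50 µg/L are reported
as supporting distribution summaries.

Predicted and measured adequacy calls for the same people form a 2×2
agreement table, summarised by Cohen's kappa (chance-corrected agreement),
sensitivity (probability a truly below-EAR person is predicted below) and
specificity (probability a truly adequate person is predicted adequate).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EAR_UG_DAY",
    "MUIC_DEFICIENCY_CUTOFF",
    "UIC_LOW_CUTOFF",
    "AdequacyClass",
    "AgreementTable",
    "MUICSummary",
    "DegenerateTableError",
    "classify_ear",
    "below_ear",
    "population_muic",
    "cross_tabulate",
    "cohens_kappa",
    "sensitivity_specificity",
    "pct_below_ear",
]

#: Adult Estimated Average Requirement for iodine, µg/day.
EAR_UG_DAY = 95.0

#: MUIC below this (µg/L) indicates population-level deficiency.
MUIC_DEFICIENCY_CUTOFF = 100.0

#: Secondary UIC cut-off (µg/L) for the low tail of the distribution.
UIC_LOW_CUTOFF = 50.0


class AdequacyClass(str, Enum):
    BELOW_EAR = "below_ear"
    AT_OR_ABOVE_EAR = "at_or_above_ear"


class DegenerateTableError(ValueError):
    """Agreement statistic undefined (empty table or chance agreement of 1)."""


def classify_ear(intake: float, ear: float = EAR_UG_DAY) -> AdequacyClass:
    """Classify a single estimated intake (µg/day) against the EAR.

    Strictly below the EAR is inadequate; exactly the EAR counts as
    adequate.
    """
    if intake < 0:
        raise ValueError("intake must be >= 0")
    return AdequacyClass.BELOW_EAR if intake < ear else AdequacyClass.AT_OR_ABOVE_EAR


def below_ear(intakes, ear: float = EAR_UG_DAY):
    """Vectorised strict below-EAR indicator; NaN propagates as NaN."""
    arr = np.asarray(intakes, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("intakes must be >= 0")
    out = np.where(np.isnan(arr), np.nan, (arr < ear).astype(float))
    return out


@dataclass(frozen=True)
class MUICSummary:
    """Population spot-UIC summary: median, deficiency flag and low tails."""

    muic: float
    deficient: bool
    pct_lt100: float
    pct_lt50: float
    n: int


def population_muic(uics: Sequence[float]) -> MUICSummary:
    """Summarise a population's spot UIC distribution.

    Returns the median UIC (µg/L), whether it falls below the 100 µg/L
    deficiency cut-off, and the percentages below 100 and 50 µg/L (the
    second being the WHO "no more than 20% below 50 µg/L" tail).
    """
    arr = np.asarray(uics, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("population_muic requires a non-empty UIC list")
    muic = float(np.median(arr))
    return MUICSummary(
        muic=muic,
        deficient=muic < MUIC_DEFICIENCY_CUTOFF,
        pct_lt100=float(np.mean(arr < MUIC_DEFICIENCY_CUTOFF) * 100.0),
        pct_lt50=float(np.mean(arr < UIC_LOW_CUTOFF) * 100.0),
        n=int(arr.size),
    )


@dataclass(frozen=True)
class AgreementTable:
    """2×2 cross-tabulation of predicted (rows) vs measured (columns) adequacy.

    ``a``: both below EAR; ``b``: predicted below / measured at-or-above;
    ``c``: predicted at-or-above / measured below; ``d``: both at-or-above.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be >= 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def pred_below(self) -> int:
        return self.a + self.b

    @property
    def meas_below(self) -> int:
        return self.a + self.c


def _as_below_mask(classes: Iterable) -> np.ndarray:
    """Coerce AdequacyClass / bool / None entries to a float below-EAR mask."""
    out = []
    for item in classes:
        if item is None:
            out.append(np.nan)
        elif isinstance(item, AdequacyClass):
            out.append(1.0 if item is AdequacyClass.BELOW_EAR else 0.0)
        elif isinstance(item, (bool, np.bool_)):
            out.append(1.0 if item else 0.0)
        else:
            value = float(item)
            if not np.isnan(value) and value not in (0.0, 1.0):
                raise ValueError(f"cannot interpret {item!r} as an adequacy class")
            out.append(value)
    return np.asarray(out, dtype=float)


def cross_tabulate(pred: Iterable, meas: Iterable) -> AgreementTable:
    """Cross-tabulate paired predicted and measured adequacy calls.

    Accepts sequences of :class:`AdequacyClass`, booleans (True = below
    EAR) or 0/1/NaN.  Pairs with a missing prediction or measurement are
    dropped (this is how participants without the Mage race indicator
    leave that equation's table).
    """
    p = _as_below_mask(pred)
    m = _as_below_mask(meas)
    if p.shape != m.shape:
        raise ValueError(f"length mismatch: {p.size} predictions vs {m.size} measurements")
    keep = ~(np.isnan(p) | np.isnan(m))
    p, m = p[keep].astype(bool), m[keep].astype(bool)
    return AgreementTable(
        a=int(np.sum(p & m)),
        b=int(np.sum(p & ~m)),
        c=int(np.sum(~p & m)),
        d=int(np.sum(~p & ~m)),
    )


def cohens_kappa(t: AgreementTable) -> float:
    """Cohen's kappa: (po - pe) / (1 - pe).

    ``po`` is the observed agreement (a + d)/n; ``pe`` the agreement
    expected by chance from the marginals,
    ``[(a+b)(a+c) + (c+d)(b+d)] / n²``.
    """
    n = t.n
    if n == 0:
        raise DegenerateTableError("empty agreement table")
    po = (t.a + t.d) / n
    pe = ((t.a + t.b) * (t.a + t.c) + (t.c + t.d) * (t.b + t.d)) / n**2
    if pe == 1.0:
        raise DegenerateTableError("chance agreement is 1; kappa undefined")
    return (po - pe) / (1.0 - pe)


def sensitivity_specificity(t: AgreementTable) -> dict:
    """Percent sensitivity and specificity for detecting below-EAR intake.

    Sensitivity = a/(a+c) × 100 (measured-below column); specificity =
    d/(b+d) × 100.  A zero margin leaves the corresponding statistic
    undefined and raises.
    """
    if t.a + t.c == 0:
        raise DegenerateTableError("no measured-below pairs; sensitivity undefined")
    if t.b + t.d == 0:
        raise DegenerateTableError("no measured-above pairs; specificity undefined")
    return {
        "sens": t.a / (t.a + t.c) * 100.0,
        "spec": t.d / (t.b + t.d) * 100.0,
    }


def pct_below_ear(classes: Iterable) -> float:
    """Percent of non-missing classifications that are below the EAR."""
    mask = _as_below_mask(classes)
    mask = mask[~np.isnan(mask)]
    if mask.size == 0:
        raise ValueError("pct_below_ear requires at least one classification")
    return float(np.mean(mask) * 100.0)
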