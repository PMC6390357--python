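"""Biologically effective dose (BED) arithmetic for SBRT prescriptions.

SBRT doses are prescribed at an isodose surface (e.g. "3 x 9 Gy @ 65%"),
meaning the tumour periphery receives 9 Gy per fraction while the isocenter
receives 9/0.65 Gy.  For dose-response modelling all prescriptions are put on
a common scale, the biologically effective dose at the isocenter under the
linear-quadratic model::

    BED_iso = n * d * (1 + d / (alpha/beta))

with ``n`` fractions, ``d`` the isocenter dose per fraction and alpha/beta
the tissue fractionation-sensitivity ratio (10 Gy for tumour control).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "Prescription",
    "BedValue",
    "InvalidPrescriptionError",
    "InfeasibleScheduleError",
    "isocenter_dose",
    "bed_iso",
    "schedule_for_bed",
]


class InvalidPrescriptionError(ValueError):
    """A prescription violates its physical constraints."""


class InfeasibleScheduleError(ValueError):
    """No physically realisable schedule attains the requested BED."""


@dataclass(frozen=True)
class Prescription:
    """A fractionation schedule as written clinically.

    Parameters
    ----------
    n_fractions:
        Number of fractions, a positive integer.
    dose_per_fraction:
        Dose per fraction in Gy *at the prescription isodose surface*.
        Zero is permitted (a null schedule); negative doses are not.
    prescription_isodose:
        The isodose line in percent of the isocenter dose, in (0, 100].
        "@ 65%" means the prescribed dose is 65% of the isocenter dose.
    alpha_beta:
        Linear-quadratic alpha/beta ratio in Gy.  Default 10 Gy (tumour).
    """

    n_fractions: int
    dose_per_fraction: float
    prescription_isodose: float = 100.0
    alpha_beta: float = 10.0

    def __post_init__(self) -> None:
        if not (isinstance(self.n_fractions, int) and self.n_fractions >= 1):
            raise InvalidPrescriptionError(
                f"n_fractions must be a positive integer, got {self.n_fractions!r}"
            )
        if not (self.dose_per_fraction >= 0 and math.isfinite(self.dose_per_fraction)):
            raise InvalidPrescriptionError(
                f"dose_per_fraction must be finite and >= 0, got {self.dose_per_fraction!r}"
            )
        if not (0 < self.prescription_isodose <= 100):
            raise InvalidPrescriptionError(
                f"prescription_isodose must lie in (0, 100], got {self.prescription_isodose!r}"
            )
        if not (self.alpha_beta > 0 and math.isfinite(self.alpha_beta)):
            raise InvalidPrescriptionError(
                f"alpha_beta must be finite and > 0, got {self.alpha_beta!r}"
            )

    def with_dose(self, dose_per_fraction: float) -> "Prescription":
        return replace(self, dose_per_fraction=dose_per_fraction)


@dataclass(frozen=True)
class BedValue:
    """A biologically effective dose at the isocenter, in Gy_10 (>= 0)."""

    bed_iso: float

    def __post_init__(self) -> None:
        if not (self.bed_iso >= 0 and math.isfinite(self.bed_iso)):
            raise InvalidPrescriptionError(f"bed_iso must be finite and >= 0, got {self.bed_iso!r}")

    def __float__(self) -> float:
        return float(self.bed_iso)

    def rounded(self, ndigits: int = 1) -> float:
        """BED rounded for reporting; the exact value stays in ``bed_iso``."""
        return round(self.bed_iso, ndigits)


def isocenter_dose(p: Prescription) -> float:
    """Dose per fraction at the isocenter, in Gy.

    The prescription surface receives ``prescription_isodose`` percent of the
    isocenter dose, so the isocenter dose is the prescribed dose divided by
    that fraction; it equals the prescribed dose when the isodose is 100%.
    """
    return p.dose_per_fraction / (p.prescription_isodose / 100.0)


def bed_iso(p: Prescription) -> BedValue:
    """BED at the isocenter, ``n*d*(1 + d/(alpha/beta))`` with d the isocenter dose.

    Exact closed form; no internal rounding.  Examples: 5 x 13 Gy @ 65%
    gives d = 20 Gy and BED = 5*20*(1 + 20/10) = 300 Gy_10.
    """
    d = isocenter_dose(p)
    return BedValue(p.n_fractions * d * (1.0 + d / p.alpha_beta))


def schedule_for_bed(
    target: BedValue | float,
    n_fractions: int,
    prescription_isodose: float = 100.0,
    alpha_beta: float = 10.0,
) -> Prescription:
    """Invert the BED formula: find the schedule delivering a target BED_iso.

    Solves ``n*d*(1 + d/ab) = target`` for the isocenter fraction dose d
    (a quadratic with a single positive root for target > 0) and reports the
    dose per fraction back at the prescription isodose surface.
    """
    bed = float(target)
    if bed <= 0:
        raise InfeasibleScheduleError(f"target BED must be positive, got {bed!r}")
    probe = Prescription(n_fractions, 0.0, prescription_isodose, alpha_beta)
    # d^2/ab + d - bed/n = 0  ->  positive root of the quadratic
    disc = 1.0 + 4.0 * bed / (n_fractions * alpha_beta)
    d_iso = alpha_beta * (math.sqrt(disc) - 1.0) / 2.0
    if d_iso <= 0:  # pragma: no cover - cannot occur for bed > 0
        raise InfeasibleScheduleError("no positive root for the requested BED")
    d_rx = d_iso * (prescription_isodose / 100.0)
    return probe.with_dose(d_rx)
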