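"""Flame-photometry ion quantification.

Standard solutions (e.g. the 10, 8, 6, 4, 2, 1, 0.5 ppm Na/K series) fit a
straight calibration line reading = slope·ppm + intercept; sample readings
are inverse-predicted to ppm, converted to tissue content as

    mmol per gram dry mass = (ppm · dilution) / (equivalent weight · 1000 · dry weight [g])

and summarised as the Na⁺/K⁺ ratio, the standard proxy for salt-stress
status (lower is better under stress).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "IonContentRecord",
    "EQUIVALENT_WEIGHTS",
    "fit_calibration",
    "mmol_per_g",
    "na_k_ratio",
]

# g per equivalent; for the monovalent Na+ and K+ these equal the atomic weights
EQUIVALENT_WEIGHTS = {"Na": 22.99, "K": 39.10}


class ExtrapolationWarning(UserWarning):
    """Inverse prediction outside the standards' concentration range."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted linear photometer response for one ion."""

    ion: str
    concentrations: tuple[float, ...]
    readings: tuple[float, ...]
    slope: float
    intercept: float
    r_squared: float

    def to_ppm(self, reading: float | np.ndarray) -> float | np.ndarray:
        """Inverse prediction ppm = (reading − intercept) / slope.

        Warns (never errors) on extrapolation beyond the standards' range.
        """
        ppm = (np.asarray(reading, dtype=float) - self.intercept) / self.slope
        lo, hi = min(self.concentrations), max(self.concentrations)
        eps = 1e-9 * (hi - lo)  # guards against float round-off at the edges
        if np.any(ppm < lo - eps) or np.any(ppm > hi + eps):
            warnings.warn(
                f"{self.ion}: inverse-predicted concentration outside the "
                f"standards' range [{lo}, {hi}] ppm",
                ExtrapolationWarning,
                stacklevel=2,
            )
        return float(ppm) if np.isscalar(reading) else ppm

    def predict_reading(self, ppm: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(ppm, dtype=float) + self.intercept


@dataclass(frozen=True)
class IonContentRecord:
    """One sample's ion content via the dry-mass formula."""

    sample_id: str
    ion: str
    reading: float
    ppm: float
    dilution: float
    equivalent_weight: float
    dry_weight_g: float

    @property
    def mmol_per_g(self) -> float:
        return mmol_per_g(self.ppm, self.dilution, self.equivalent_weight, self.dry_weight_g)


def fit_calibration(
    standards_ppm: Sequence[float],
    readings: Sequence[float],
    ion: str = "Na",
) -> CalibrationCurve:
    """Ordinary least-squares calibration line through the standards.

    Requires at least 3 distinct positive standard concentrations and a
    positive fitted slope (a flat or inverted photometer response is a
    hardware fault, not a fit).
    """
    c = np.asarray(standards_ppm, dtype=float)
    r = np.asarray(readings, dtype=float)
    if c.shape != r.shape:
        raise ValueError("standards and readings must have equal length")
    if c.size < 3:
        raise ValueError("need at least 3 calibration standards")
    if np.any(c <= 0):
        raise ValueError("standard concentrations must be positive")
    if len(set(c.tolist())) != c.size:
        raise ValueError("standard concentrations must be distinct")
    fit = stats.linregress(c, r)
    if fit.slope <= 0:
        raise ValueError(f"non-positive calibration slope ({fit.slope:g}): photometer response not monotone")
    return CalibrationCurve(
        ion=ion,
        concentrations=tuple(float(x) for x in c),
        readings=tuple(float(x) for x in r),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def mmol_per_g(ppm: float, dilution: float, equivalent_weight: float, dry_weight_g: float) -> float:
    """Tissue ion content, mmol per gram dry mass.

    (ppm · dilution factor) / (equivalent weight · 1000 · dry weight in g).
    """
    for name, v in (("ppm", ppm), ("dilution", dilution), ("equivalent_weight", equivalent_weight), ("dry_weight_g", dry_weight_g)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return (ppm * dilution) / (equivalent_weight * 1000.0 * dry_weight_g)


def na_k_ratio(na_content: float, k_content: float) -> float:
    """Sodium content divided by potassium content (same units)."""
    if k_content <= 0:
        raise ValueError(f"potassium content must be positive, got {k_content}")
    if na_content < 0:
        raise ValueError(f"sodium content must be non-negative, got {na_content}")
    return na_content / k_content
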