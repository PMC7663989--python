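"""CPUE standardization and log-scale abundance classes.

Trawl catches are standardized to catch per unit effort (CPUE) in fish per
1,000 m^2 of area swept, assuming 100% catchability.  Mean CPUE within a
spatial unit is then discretized onto an ordinal log-scale of habitat
quality: Unsuitable (0 fish/1,000 m^2), Marginal (1), Moderate (2-10) and
Optimal (11-100).  Class boundaries sit halfway between the labelled
densities (0.5, 1.5, 10.5), i.e. rounding to the nearest labelled class.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np

__all__ = [
    "AbundanceClass",
    "CLASS_BOUNDS",
    "standardize_cpue",
    "classify_abundance",
    "appropriate",
]


class AbundanceClass(IntEnum):
    """Ordinal habitat-quality class, ordered by the density it supports."""

    UNSUITABLE = 0
    MARGINAL = 1
    MODERATE = 2
    OPTIMAL = 3

    @property
    def label(self) -> str:
        return self.name.capitalize()


#: Representative (lower, upper) density of each class in fish/1,000 m^2.
#: Used by population estimation: minimum estimates use the lower bound,
#: maximum estimates the upper bound.
CLASS_BOUNDS: dict[AbundanceClass, tuple[float, float]] = {
    AbundanceClass.UNSUITABLE: (0.0, 0.0),
    AbundanceClass.MARGINAL: (1.0, 1.0),
    AbundanceClass.MODERATE: (1.5, 10.0),
    AbundanceClass.OPTIMAL: (10.5, 100.0),
}

# Decision boundaries between classes (round-to-nearest-labelled-class).
_EDGES = (0.5, 1.5, 10.5)


def standardize_cpue(count, area_swept_m2):
    """Catch per unit effort in fish/1,000 m^2.

    Parameters
    ----------
    count : int or array-like
        Number of fish caught in the tow.
    area_swept_m2 : float or array-like
        Area swept by the trawl in m^2; must be positive.
    """
    count = np.asarray(count, dtype=float)
    area = np.asarray(area_swept_m2, dtype=float)
    if np.any(area <= 0):
        raise ValueError("area_swept_m2 must be positive")
    out = count * 1000.0 / area
    return float(out) if out.ndim == 0 else out


def classify_abundance(mean_cpue, any_presence=False):
    """Map mean CPUE to an abundance class.

    ``mean_cpue < 0.5`` is Unsuitable unless ``any_presence`` is set, in
    which case a positive mean backed by at least one captured fish is
    promoted to Marginal (the smallest positive CPUE in a trawl record is
    a presence, not an absence).  ``[0.5, 1.5)`` -> Marginal, ``[1.5,
    10.5)`` -> Moderate, ``>= 10.5`` -> Optimal.

    Accepts scalars or arrays; returns an ``AbundanceClass`` for scalar
    input, an integer array of class codes otherwise.
    """
    cpue = np.asarray(mean_cpue, dtype=float)
    if np.any(cpue < 0):
        raise ValueError("mean_cpue must be non-negative")
    presence = np.asarray(any_presence, dtype=bool)
    codes = np.digitize(cpue, _EDGES)  # 0..3
    codes = np.where((codes == 0) & presence & (cpue > 0), 1, codes)
    if cpue.ndim == 0:
        return AbundanceClass(int(codes))
    return codes.astype(np.int8)


def appropriate(cls) -> bool | np.ndarray:
    """True for classes supporting >= 2 fish/1,000 m^2 (Moderate, Optimal)."""
    codes = np.asarray(cls, dtype=int)
    out = codes >= AbundanceClass.MODERATE
    return bool(out) if out.ndim == 0 else out
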