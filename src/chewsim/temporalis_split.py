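"""Decomposition of the temporalis principal vector into its three parts.

The temporalis principal force FT is distributed over the anterior, middle
and posterior parts in fixed proportions, following the assumption that
muscle force is proportional to physiological cross-sectional area. The
part-level PCSAs are not published; the fractions used here are the fixed
constants recovered by least squares from the published component tables
(per-cell division of every component force by its principal force gives
the same three values across all ten food-side cases).

The split conserves the scalar sum exactly: FAT + FMT + FPT = FT. The
sagittal-projection direction angles of the principal vector and the three
components are carried as metadata; the published tables satisfy scalar
(not vector) additivity, so directions do not enter the decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: PCSA-proportional force fractions (anterior, middle, posterior).
FRACTIONS = {
    "temporalis_anterior": 0.4799,
    "temporalis_middle": 0.2900,
    "temporalis_posterior": 0.2301,
}

#: Sagittal-projection angles (deg from the horizontal sagittal axis) of the
#: principal vector and each component line of action.
DIRECTION_ANGLES_DEG = {
    "temporalis": 58.0,
    "temporalis_anterior": 76.0,
    "temporalis_middle": 42.0,
    "temporalis_posterior": 22.0,
}


@dataclass(frozen=True)
class TemporalisComponents:
    """Component magnitudes (N) of one principal temporalis force."""

    FAT: float
    FMT: float
    FPT: float
    fractions: dict = field(default_factory=lambda: dict(FRACTIONS))
    angles_deg: dict = field(default_factory=lambda: dict(DIRECTION_ANGLES_DEG))

    @property
    def total(self) -> float:
        return self.FAT + self.FMT + self.FPT


def split(FT: float) -> TemporalisComponents:
    """Split a principal temporalis magnitude into its three components.

    The posterior fraction is taken as the remainder so the scalar sum is
    conserved exactly in arithmetic.
    """
    if FT < 0:
        raise ValueError("temporalis principal force must be non-negative")
    fat = FRACTIONS["temporalis_anterior"] * FT
    fmt = FRACTIONS["temporalis_middle"] * FT
    return TemporalisComponents(FAT=fat, FMT=fmt, FPT=FT - fat - fmt)


def split_series(FT: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised split of a principal force series; keys are the part
    names, values the component series (N)."""
    FT = np.asarray(FT, dtype=float)
    if np.any(FT < -1e-12):
        raise ValueError("temporalis principal force series must be non-negative")
    fat = FRACTIONS["temporalis_anterior"] * FT
    fmt = FRACTIONS["temporalis_middle"] * FT
    return {
        "temporalis_anterior": fat,
        "temporalis_middle": fmt,
        "temporalis_posterior": FT - fat - fmt,
    }
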