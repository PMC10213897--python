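"""Food-dependent chewing path of the incisal point.

During unilateral chewing the incisal point traces an ellipse-like loop in
the frontal plane whose height follows the food height. The force analysis
runs on the closing limb: from BP, the point where chewing begins at the
inferior-lateral extremity of the loop (deviated toward the working side and
open by the food height), the incisor sweeps medially and upward into the
intercuspal end position at the coordinate origin, traversed at constant
speed v_t. The lateral deviation decreases monotonically along the closing
stroke and the terminal approach into intercuspation is dominantly vertical
(lateral offset ~ closure_gap**q with q > 1). The opening limb (generated
for completeness only) drops near-vertically and deviates laterally toward
BP, closing the loop.

The lateral width of the loop is not free: it is solved per food so that
the closing arc length equals v_t * t_chew, which reconciles the catalogued
food heights with the catalogued chewing times (arc factor approximately
1.11 * h for every food).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .foodbank import FoodSpecimen

_DENSE = 4096
RETURN_EXPONENT = 1.8


def _arc_table(w: float, h: float, q: float = RETURN_EXPONENT):
    """Cumulative arc length of the closing stroke
    (w * zeta**q, -h * zeta) with zeta(u) = (1 + cos(pi u)) / 2."""
    u = np.linspace(0.0, 1.0, _DENSE + 1)
    zeta = 0.5 * (1.0 + np.cos(np.pi * u))
    dzeta = -0.5 * np.pi * np.sin(np.pi * u)
    dy = w * q * zeta ** (q - 1.0) * dzeta
    dz = -h * dzeta
    speed = np.hypot(dy, dz)
    s = np.concatenate([[0.0], np.cumsum((speed[1:] + speed[:-1]) * 0.5 * np.diff(u))])
    return u, s


@dataclass
class ChewPath:
    """Closing trajectory of the incisal point in the frontal plane (y, z).

    The stroke starts at BP = (lateral_sign * width, -height) and ends at
    the origin; ``lateral_sign`` is -1 for right-side chewing (y points
    left).
    """

    food_id: str
    height: float
    width: float  # lateral deviation at BP, m
    t_chew: float
    v_t: float
    lateral_sign: float
    arc_length: float
    return_exponent: float
    _u_of_s: PchipInterpolator = field(repr=False)

    @property
    def bp(self) -> tuple[float, float]:
        """Start point of chewing (y, z)."""
        return (self.lateral_sign * self.width, -self.height)

    @property
    def aspect(self) -> float:
        """Lateral width over height."""
        return self.width / self.height

    @property
    def arc_factor(self) -> float:
        return self.arc_length / self.height

    def _point(self, u: np.ndarray):
        zeta = 0.5 * (1.0 + np.cos(np.pi * u))
        y = self.lateral_sign * self.width * zeta**self.return_exponent
        z = -self.height * zeta
        return y, z

    def closing_position(self, t):
        """Frontal-plane position (y, z) at time t, constant-speed closing."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < -1e-12) or np.any(t_arr > self.t_chew * (1 + 1e-12)):
            raise ValueError(f"t outside [0, {self.t_chew}]: {t!r}")
        s = np.clip(t_arr * self.v_t, 0.0, self.arc_length)
        u = np.clip(self._u_of_s(s), 0.0, 1.0)
        y, z = self._point(u)
        if np.ndim(t) == 0:
            return float(y), float(z)
        return y, z

    def closure(self, t):
        """Height change of the food, dh(t) = h + z(t): 0 at t=0, h at t_chew."""
        _, z = self.closing_position(t)
        return self.height + np.asarray(z)

    def cycle_samples(self, n: int = 200) -> pd.DataFrame:
        """Full chewing loop for export: the closing limb plus an opening
        limb that drops from the origin and swings out to BP, closing the
        loop. Only the closing limb drives the force analysis."""
        t = np.linspace(0.0, self.t_chew, n + 1)
        y, z = self.closing_position(t)
        closing = pd.DataFrame({"t_s": t, "y_m": y, "z_m": z, "phase": "closing"})
        zeta = np.linspace(0.0, 1.0, n + 1)
        q = self.return_exponent
        yo = self.lateral_sign * self.width * (1.0 - (1.0 - zeta) ** q)
        zo = -self.height * zeta
        opening = pd.DataFrame({"t_s": np.nan, "y_m": yo, "z_m": zo, "phase": "opening"})
        return pd.concat([closing, opening], ignore_index=True)


def make_path(
    food: FoodSpecimen,
    v_t: float = 0.02,
    working_side: str = "right",
    aspect: float | str = "auto",
    return_exponent: float = RETURN_EXPONENT,
) -> ChewPath:
    """Build the closing chewing path for a food.

    With ``aspect='auto'`` (default) the lateral width is solved so that
    the closing arc length equals v_t * t_chew; a numeric aspect
    (width / height) overrides it, in which case the constant speed is
    rescaled to keep the duration at t_chew.
    """
    if food.h <= 0:
        raise ValueError("food height must be positive")
    if v_t <= 0:
        raise ValueError("closing speed v_t must be positive")
    if working_side not in ("right", "left"):
        raise ValueError("working_side must be 'right' or 'left'")
    h, target = food.h, v_t * food.t_chew

    def total(w):
        return _arc_table(w, h, return_exponent)[1][-1]

    if aspect == "auto":
        if target <= h:
            raise ValueError(
                f"chewing time too short: v_t*t_chew = {target:.4g} m cannot "
                f"cover the food height {h:.4g} m"
            )
        w = brentq(lambda w: total(w) - target, 1e-9, 2.0 * h, xtol=1e-14)
    else:
        if aspect <= 0:
            raise ValueError("aspect must be positive")
        w = float(aspect) * h

    u, s = _arc_table(w, h, return_exponent)
    arc = s[-1]
    return ChewPath(
        food_id=food.id,
        height=h,
        width=w,
        t_chew=food.t_chew,
        v_t=arc / food.t_chew,
        lateral_sign=-1.0 if working_side == "right" else 1.0,
        arc_length=arc,
        return_exponent=return_exponent,
        _u_of_s=PchipInterpolator(s, u),
    )
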