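"""Food specimens and their force-deformation characteristics.

A food specimen resists jaw closure with a force that depends on how far it
has been compressed: the load characteristic F = f(dh), with dh the reduction
of specimen height. The published characteristics exist only as graphs, so
this module provides a parametric stand-in family: a power-law rise to a peak
force at a stated fraction of full closure, followed by a smooth post-peak
envelope that either collapses (brittle foods: chocolate, carrot, apple) or
settles onto a plateau (ductile foods: chocolate bar, sausage).

Peak forces are recovered by inverting the published force-proportionality
relation F_H = R_F * F_max using the working-side masseter row, the only
route available since maximum occlusal forces are not tabulated. Peak
positions default to the published ratio of contraction-at-maximum to total
contraction of the working masseter, which transfers to closure fraction
because muscle contraction is monotone in closure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd

from . import fixtures

FOOD_IDS = fixtures.FOOD_IDS

#: Closure fraction at which the resistance force peaks (dq_H/dq_C of the
#: working masseter, per food).
DEFAULT_P_PEAK = {"d": 0.50, "b": 0.47, "a": 0.23, "c": 0.27, "s": 0.23}

#: Post-peak behaviour class per food.
DEFAULT_SHAPE = {"d": "brittle", "b": "ductile", "a": "brittle", "c": "brittle", "s": "ductile"}

#: Shape-class parameters of the post-peak envelope
#: plateau: residual force level as a fraction of the peak;
#: width: decay scale of the drop toward the plateau, as a fraction of h.
SHAPE_PARAMS = {
    "brittle": {"plateau": 0.02, "width": 0.08},
    "ductile": {"plateau": 0.55, "width": 0.15},
}


class UnknownFoodError(KeyError):
    pass


@dataclass(frozen=True)
class FoodSpecimen:
    """Mean specimen geometry (m) and chewing time (s) for one food."""

    id: str
    label: str
    h: float
    w: float
    l: float
    t_chew: float

    def __post_init__(self):
        if self.h <= 0 or self.t_chew <= 0:
            raise ValueError("food height and chewing time must be positive")


@dataclass(frozen=True)
class FoodCurve:
    """Parametric force-deformation characteristic F = f(dh).

    F(0) = 0, F >= 0 on [0, h], and the maximum F_peak is attained at
    dh = p_peak * h. ``rise_exponent`` shapes the pre-peak power-law rise;
    ``plateau`` and ``width`` shape the post-peak envelope.
    """

    food: FoodSpecimen
    F_peak: float
    p_peak: float
    shape: str
    rise_exponent: float = 1.1
    plateau: float | None = None
    width: float | None = None

    def __post_init__(self):
        if not 0 < self.p_peak < 1:
            raise ValueError("p_peak must lie in (0, 1)")
        if self.F_peak <= 0:
            raise ValueError("F_peak must be positive")
        if self.shape not in SHAPE_PARAMS:
            raise ValueError(f"shape must be one of {sorted(SHAPE_PARAMS)}")
        for field in ("plateau", "width"):
            if getattr(self, field) is None:
                object.__setattr__(self, field, SHAPE_PARAMS[self.shape][field])


def catalog(food_id: str) -> FoodSpecimen:
    """Return the catalogued specimen for ``food_id``."""
    table = fixtures.food_catalogue()
    if food_id not in table.index:
        raise UnknownFoodError(
            f"unknown food id {food_id!r}; valid ids: {', '.join(FOOD_IDS)}"
        )
    row = table.loc[food_id]
    return FoodSpecimen(
        id=food_id,
        label=row.label,
        h=float(row.h_m),
        w=float(row.w_m),
        l=float(row.l_m),
        t_chew=float(row.t_chew_s),
    )


def default_peak_force(food_id: str) -> float:
    """Peak resistance force (N), from the working-masseter maximum force
    divided by its force-proportionality coefficient.

    This inversion is the calibration used to build the default curves; the
    source tables never print the maximum occlusal forces themselves.
    """
    catalog(food_id)  # validates the id
    summary = fixtures.muscle_summary()
    row = summary[
        (summary.food == food_id)
        & (summary.side == "W")
        & (summary.muscle == "masseter")
    ]
    return float(row.F_H_N.iloc[0]) / fixtures.force_ratio("masseter", "W")


def default_curve(food_id: str, **overrides) -> FoodCurve:
    """The default parametric characteristic for a catalogued food."""
    food = catalog(food_id)
    kwargs = dict(
        food=food,
        F_peak=default_peak_force(food_id),
        p_peak=DEFAULT_P_PEAK[food_id],
        shape=DEFAULT_SHAPE[food_id],
    )
    kwargs.update(overrides)
    return FoodCurve(**kwargs)


def force_at(curve: FoodCurve, dh) -> np.ndarray | float:
    """Evaluate the characteristic at height change ``dh`` (m).

    Accepts scalars or arrays; raises on dh outside [0, h].
    """
    dh_arr = np.asarray(dh, dtype=float)
    h = curve.food.h
    if np.any(dh_arr < -1e-12) or np.any(dh_arr > h + 1e-12):
        raise ValueError(f"dh outside [0, {h}]: {dh!r}")
    dh_arr = np.clip(dh_arr, 0.0, h)
    dh_p = curve.p_peak * h
    x = dh_arr / dh_p
    rising = curve.F_peak * np.power(np.minimum(x, 1.0), curve.rise_exponent)
    s = (dh_arr - dh_p) / h
    envelope = curve.plateau + (1.0 - curve.plateau) * np.exp(
        -((np.maximum(s, 0.0) / curve.width) ** 2)
    )
    out = np.where(x <= 1.0, rising, curve.F_peak * envelope)
    return float(out) if np.isscalar(dh) or np.ndim(dh) == 0 else out


def time_profiles(
    curve: FoodCurve,
    closure: Callable[[np.ndarray], np.ndarray],
    n_steps: int = 200,
) -> pd.DataFrame:
    """Decompose the characteristic into time series F(t) and dh(t).

    ``closure`` maps t in [0, t_chew] to the height change dh; it must start
    at 0, end at h and be non-decreasing (checked on the sampled grid).
    """
    food = curve.food
    t = np.linspace(0.0, food.t_chew, n_steps + 1)
    dh = np.asarray(closure(t), dtype=float)
    if abs(dh[0]) > 1e-9 or abs(dh[-1] - food.h) > 1e-9:
        raise ValueError("closure must map 0 -> 0 and t_chew -> h")
    if np.any(np.diff(dh) < -1e-12):
        raise ValueError("closure must be non-decreasing")
    dh = np.clip(dh, 0.0, food.h)
    return pd.DataFrame({"t_s": t, "dh_m": dh, "F_N": force_at(curve, dh)})


def sample_curve(
    curve: FoodCurve,
    n: int = 200,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample the characteristic on a uniform dh grid as (dh_m, F_N).

    ``noise_sd`` (N) adds seeded Gaussian noise for robustness experiments;
    it is off by default and never used by the simulation pipeline.
    """
    dh = np.linspace(0.0, curve.food.h, n + 1)
    F = np.asarray(force_at(curve, dh), dtype=float)
    if noise_sd > 0.0:
        if rng is None:
            raise ValueError("noisy sampling requires an explicit rng")
        F = np.maximum(F + rng.normal(0.0, noise_sd, F.shape), 0.0)
        F[0] = 0.0
    return pd.DataFrame({"dh_m": dh, "F_N": F})


def with_noise(curve: FoodCurve, **overrides) -> FoodCurve:
    """Convenience for tests: shallow parameter variation of a curve."""
    return replace(curve, **overrides)
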