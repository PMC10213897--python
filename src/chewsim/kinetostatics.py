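"""Quasi-static muscle-force solve over the prescribed closing motion.

At every time step the mandible is in equilibrium under the food reaction at
the molar load point IW, four active muscle forces (temporalis and the
masseter+medial-pterygoid resultant V, per side) and the two condylar
contact reactions. In the force model both condyles are point-on-plane
contacts (the published structure: two joints with three rotations and two
displacements each leaves four degrees of freedom), so four equilibrium
components determine the four muscle unknowns.

Two equivalent formulations are implemented: the production solver projects
all wrenches onto a basis of the four contact-compatible virtual motions
(virtual work); an independent Newton-Euler route solves the full six
equations with the two contact normal magnitudes as extra unknowns. Their
agreement is a standing cross-check.

Inertia and gravity are omitted: at the prescribed closing speed of
0.02 m/s, mandibular inertia forces are orders of magnitude below occlusal
forces (an optional inertia hook point exists but is off by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from .anatomy import AnatomyModel
from .foodbank import FoodCurve, force_at
from .kinematics import MandiblePose, MandibleTrajectory
from .temporalis_split import split_series

EQUILIBRIUM_TOL = 1e-6  # N (generalised force residual)
ORACLE_TOL = 1e-3  # relative, virtual-work vs Newton-Euler

_ACTUATORS = (("temporalis", "W"), ("temporalis", "N"), ("V", "W"), ("V", "N"))


class KinetostaticsError(RuntimeError):
    pass


def _wrench(force_dir: np.ndarray, point: np.ndarray) -> np.ndarray:
    """Six-vector [f, p x f] paired with twists (v, omega) about the origin."""
    return np.concatenate([force_dir, np.cross(point, force_dir)])


def _step_geometry(model: AnatomyModel, R: np.ndarray):
    """Current muscle unit lines, contact rows and load point for a pose."""
    lines = []
    for muscle, side in _ACTUATORS:
        origin, ins0 = model.attachment(muscle, side)
        ins = model.transform_point(ins0, R)
        u = origin - ins
        u = u / np.linalg.norm(u)
        lines.append((u, ins))
    cw = model.condyle_W  # invariant under the pose
    cn = model.transform_point(model.condyle_N, R)
    contacts = [(model.guide_normal_W, cw), (model.guide_normal_N, cn)]
    iw = model.transform_point(model.IW, R)
    return lines, contacts, iw


def solve_step(
    model: AnatomyModel,
    pose: MandiblePose | np.ndarray,
    food_force: float,
    mode: str = "validate",
    extra_wrench: np.ndarray | None = None,
) -> dict:
    """Solve one step's equilibrium; returns muscle force magnitudes (N),
    contact reactions and the residual diagnostics.

    The food force acts at IW along the occlusal-plane normal, opposing
    closure (pushing the mandible open). mode='validate' raises on negative
    muscle forces; 'exploratory' warns and keeps the signed values.
    """
    if food_force < 0:
        raise ValueError("food force must be non-negative")
    R = pose.R if isinstance(pose, MandiblePose) else np.asarray(pose)
    lines, contacts, iw = _step_geometry(model, R)
    W = np.column_stack([_wrench(u, p) for u, p in lines])
    w_food = _wrench(-model.occlusal_normal * food_force, iw)
    if extra_wrench is not None:
        w_food = w_food + np.asarray(extra_wrench, dtype=float)
    C = np.vstack([_wrench(n, p) for n, p in contacts])
    Z = null_space(C)
    if Z.shape[1] != 4:
        raise KinetostaticsError("contact constraints do not leave four motion freedoms")
    A = Z.T @ W
    b = -Z.T @ w_food
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e10:
        raise KinetostaticsError(
            f"singular muscle-force system (cond={cond:.2e}) at pose t={getattr(pose, 't', float('nan'))}"
        )
    f = np.linalg.solve(A, b)
    residual = float(np.max(np.abs(A @ f - b)))
    if residual > EQUILIBRIUM_TOL * max(1.0, food_force):
        raise KinetostaticsError(f"equilibrium residual {residual:.3e} exceeds tolerance")
    if mode == "validate" and np.any(f < -1e-9 * max(1.0, food_force)):
        raise KinetostaticsError(
            f"negative muscle force at t={getattr(pose, 't', float('nan'))}: {f} "
            "(model infeasible at this pose)"
        )
    # contact reactions from the full force balance
    N = np.column_stack([_wrench(n, p) for n, p in contacts])
    rhs = -(W @ f + w_food)
    reactions, *_ = np.linalg.lstsq(N, rhs, rcond=None)
    return {
        "FT_W": float(f[0]),
        "FT_N": float(f[1]),
        "FV_W": float(f[2]),
        "FV_N": float(f[3]),
        "R_W": float(reactions[0]),
        "R_N": float(reactions[1]),
        "residual": residual,
        "condition": float(cond),
    }


def solve_step_newton_euler(
    model: AnatomyModel, pose: MandiblePose | np.ndarray, food_force: float
) -> dict:
    """Independent formulation: full six-equation force/moment balance with
    the two condylar contact normal magnitudes as additional unknowns."""
    if food_force < 0:
        raise ValueError("food force must be non-negative")
    R = pose.R if isinstance(pose, MandiblePose) else np.asarray(pose)
    lines, contacts, iw = _step_geometry(model, R)
    M = np.column_stack(
        [_wrench(u, p) for u, p in lines] + [_wrench(n, p) for n, p in contacts]
    )
    w_food = _wrench(-model.occlusal_normal * food_force, iw)
    x = np.linalg.solve(M, -w_food)
    return {
        "FT_W": float(x[0]),
        "FT_N": float(x[1]),
        "FV_W": float(x[2]),
        "FV_N": float(x[3]),
        "R_W": float(x[4]),
        "R_N": float(x[5]),
    }


def _decompose_v(model: AnatomyModel, R: np.ndarray, fv: float, side: str):
    """Split the resultant V force into masseter and medial pterygoid parts
    along the two muscles' current anatomical directions (planar vector
    decomposition in the plane they span)."""
    dirs = []
    for muscle in ("masseter", "medial_pterygoid", "V"):
        origin, ins0 = model.attachment(muscle, side)
        ins = model.transform_point(ins0, R)
        u = origin - ins
        dirs.append(u / np.linalg.norm(u))
    u_m, u_mp, u_v = dirs
    B = np.column_stack([u_m, u_mp])
    coef, *_ = np.linalg.lstsq(B, fv * u_v, rcond=None)
    return float(coef[0]), float(coef[1])


@dataclass
class MuscleForceSolution:
    """Active muscle force time series (N) with the masseter/medial
    pterygoid decomposition, temporalis components, food force and TMJ
    contact reactions."""

    t: np.ndarray
    F_food: np.ndarray
    FT_W: np.ndarray
    FT_N: np.ndarray
    FV_W: np.ndarray
    FV_N: np.ndarray
    FM_W: np.ndarray
    FM_N: np.ndarray
    FMP_W: np.ndarray
    FMP_N: np.ndarray
    R_W: np.ndarray
    R_N: np.ndarray
    max_residual: float = 0.0
    min_raw_force: float = 0.0  # most negative pre-clamp muscle force, N
    parts: dict = field(default_factory=dict)  # (part, side) -> array

    def series(self, muscle: str, side: str) -> np.ndarray:
        table = {
            "masseter": {"W": self.FM_W, "N": self.FM_N},
            "medial_pterygoid": {"W": self.FMP_W, "N": self.FMP_N},
            "temporalis": {"W": self.FT_W, "N": self.FT_N},
            "V": {"W": self.FV_W, "N": self.FV_N},
        }
        if muscle in table:
            return table[muscle][side]
        if (muscle, side) in self.parts:
            return self.parts[(muscle, side)]
        raise KeyError(f"no force series for {muscle!r} side {side!r}")

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "t_s": self.t,
            "F_i_N": self.F_food,
            "FT_W_N": self.FT_W,
            "FT_N_N": self.FT_N,
            "FV_W_N": self.FV_W,
            "FV_N_N": self.FV_N,
            "FM_W_N": self.FM_W,
            "FM_N_N": self.FM_N,
            "FMP_W_N": self.FMP_W,
            "FMP_N_N": self.FMP_N,
            "R_TMJ_W_N": self.R_W,
            "R_TMJ_N_N": self.R_N,
        }
        short = {
            "temporalis_anterior": "FAT",
            "temporalis_middle": "FMT",
            "temporalis_posterior": "FPT",
        }
        for (part, side), series in sorted(self.parts.items()):
            cols[f"{short[part]}_{side}_N"] = series
        return pd.DataFrame(cols)


def run_forces(
    model: AnatomyModel,
    trajectory: MandibleTrajectory,
    food_curve: FoodCurve,
    mode: str = "validate",
    inertia_hook=None,
) -> MuscleForceSolution:
    """Per-step equilibrium over the closing phase.

    The food load history follows the path closure: F(t) = f(dh(t)). The
    resultant V forces are decomposed into masseter and medial pterygoid
    parts and the temporalis principal vectors into their three components.

    ``inertia_hook(trajectory, i)`` may supply an additional six-component
    wrench per step (e.g. estimated inertia forces); it is off by default —
    at the prescribed closing speed inertia is negligible.
    """
    if trajectory.path.food_id != food_curve.food.id:
        raise KinetostaticsError(
            f"trajectory is for food {trajectory.path.food_id!r} but curve for "
            f"{food_curve.food.id!r}"
        )
    t = trajectory.t
    dh = np.clip(trajectory.path.closure(t), 0.0, food_curve.food.h)
    F = np.asarray(force_at(food_curve, dh), dtype=float)
    n = len(t)
    keys = ("FT_W", "FT_N", "FV_W", "FV_N", "R_W", "R_N")
    out = {k: np.zeros(n) for k in keys}
    fm = {s: np.zeros(n) for s in ("W", "N")}
    fmp = {s: np.zeros(n) for s in ("W", "N")}
    max_res = 0.0
    for i, pose in enumerate(trajectory.poses):
        extra = inertia_hook(trajectory, i) if inertia_hook is not None else None
        step = solve_step(model, pose, F[i], mode=mode, extra_wrench=extra)
        for k in keys:
            out[k][i] = step[k]
        max_res = max(max_res, step["residual"])
        for side in ("W", "N"):
            fv = step[f"FV_{side}"]
            fm[side][i], fmp[side][i] = _decompose_v(model, pose.R, fv, side)
    min_raw = float(min(np.min(out[k]) for k in ("FT_W", "FT_N", "FV_W", "FV_N")))
    if mode == "exploratory":
        n_neg = int(
            sum(np.sum(out[k] < -1e-9) for k in ("FT_W", "FT_N", "FV_W", "FV_N"))
        )
        if n_neg:
            warnings.warn(
                f"{n_neg} negative muscle-force samples clamped to zero "
                "(model infeasible at those poses)",
                stacklevel=2,
            )
        for k in ("FT_W", "FT_N", "FV_W", "FV_N"):
            np.clip(out[k], 0.0, None, out=out[k])
    sol = MuscleForceSolution(
        t=t,
        F_food=F,
        FT_W=out["FT_W"],
        FT_N=out["FT_N"],
        FV_W=out["FV_W"],
        FV_N=out["FV_N"],
        FM_W=fm["W"],
        FM_N=fm["N"],
        FMP_W=fmp["W"],
        FMP_N=fmp["N"],
        R_W=out["R_W"],
        R_N=out["R_N"],
        max_residual=max_res,
        min_raw_force=min_raw,
    )
    sol.parts = {
        (part, side): series
        for side in ("W", "N")
        for part, series in split_series(sol.series("temporalis", side)).items()
    }
    return sol
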