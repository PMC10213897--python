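"""Derived muscle parameters and summary tables.

From a trajectory (muscle lengths) and a force solution this module
computes, per food, muscle and side: the maximum force F_H and its time
t_H, the contraction at maximum force dq_H and the total contraction dq_C,
the secant stiffness K = F_H / dq_H, and the intrinsic strength
k = F_H / PCSA. Across foods it computes the proportionality coefficients
R_F = F_H / F_max and R_q = dq_C / h, and the side-asymmetry summaries.
A tangent (non-linear) stiffness K(dq) = dF/d(dq) is available from a
monotone fit of the force-contraction pattern on the rising limb.

All functions operate on plain DataFrames in the schema produced by
:func:`summarize`, so they apply equally to simulation output and to the
bundled published tables (:func:`chewsim.fixtures.reference_metrics_table`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from . import fixtures
from .anatomy import PCSA, AnatomyModel, PRINCIPAL_MUSCLES, TEMPORALIS_PARTS
from .foodbank import catalog
from .kinematics import MandibleTrajectory
from .kinetostatics import MuscleForceSolution

_GROUP_HIGH = ("d", "c")  # hard/brittle foods with high stiffness
_GROUP_LOW = ("b", "a", "s")


class MetricsError(ValueError):
    pass


def intrinsic_strength(F_H: float, pcsa: float) -> float:
    """k = F_H / PCSA (N/m^2)."""
    if pcsa <= 0:
        raise MetricsError("PCSA must be positive")
    return F_H / pcsa


def secant_stiffness(F_H: float, dq_H: float) -> float:
    """K = F_H / dq_H (N/m), the linear stiffness at the force maximum."""
    if dq_H <= 0:
        raise MetricsError("contraction at maximum force must be positive")
    return F_H / dq_H


def summarize(
    solution: MuscleForceSolution,
    trajectory: MandibleTrajectory,
    model: AnatomyModel,
    food_id: str,
    include_parts: bool = True,
) -> pd.DataFrame:
    """Per-muscle, per-side summary rows for one simulated food.

    Temporalis components inherit the principal intrinsic strength (the
    PCSA-proportional split leaves force/PCSA unchanged). All-zero force
    series produce flagged rows without K or k.
    """
    muscles = PRINCIPAL_MUSCLES + (TEMPORALIS_PARTS if include_parts else ())
    rows = []
    for muscle in muscles:
        for side in ("W", "N"):
            series = solution.series(muscle, side)
            q = trajectory.lengths[(muscle, side)]
            i_h = int(np.argmax(series))
            F_H = float(series[i_h])
            dq_H = float(q[0] - q[i_h])
            dq_C = float(q[0] - q[-1])
            row = {
                "food": food_id,
                "side": side,
                "muscle": muscle,
                "F_H_N": F_H,
                "t_H_s": float(trajectory.t[i_h]),
                "dq_H_m": dq_H,
                "dq_C_m": dq_C,
                "flag": "",
            }
            if F_H <= 0.0 or dq_H <= 0.0:
                row.update({"K_N_per_m": np.nan, "k_N_per_m2": np.nan, "flag": "no_load"})
            else:
                principal = muscle if muscle in PCSA else "temporalis"
                principal_F = float(np.max(solution.series(principal, side)))
                row["K_N_per_m"] = secant_stiffness(F_H, dq_H)
                row["k_N_per_m2"] = intrinsic_strength(principal_F, PCSA[principal])
            rows.append(row)
    return pd.DataFrame(rows)


def proportionality(table: pd.DataFrame, f_max: dict[str, float]) -> pd.DataFrame:
    """Across-food proportionality coefficients per muscle and side.

    ``f_max`` maps food id to the maximum occlusal force (N). Returns the
    across-food mean and coefficient of variation of R_F = F_H / F_max and
    R_q = dq_C / h.
    """
    foods = sorted(table.food.unique())
    heights = {f: catalog(f).h for f in foods}
    for f in foods:
        if f not in f_max or f_max[f] <= 0:
            raise MetricsError(f"missing or non-positive maximum occlusal force for food {f!r}")
        if heights[f] <= 0:
            raise MetricsError(f"non-positive height for food {f!r}")
    out = []
    for (muscle, side), grp in table.groupby(["muscle", "side"]):
        rf = np.array([r.F_H_N / f_max[r.food] for r in grp.itertuples()])
        rq = np.array([r.dq_C_m / heights[r.food] for r in grp.itertuples()])
        out.append(
            {
                "muscle": muscle,
                "side": side,
                "n_foods": len(grp),
                "R_F": float(rf.mean()),
                "R_F_cv": float(rf.std(ddof=0) / rf.mean()) if rf.mean() else np.nan,
                "R_q": float(rq.mean()),
                "R_q_cv": float(rq.std(ddof=0) / rq.mean()) if rq.mean() else np.nan,
            }
        )
    return pd.DataFrame(out)


def _require_complete(table: pd.DataFrame) -> None:
    missing = []
    for food in fixtures.FOOD_IDS:
        for side in ("W", "N"):
            for muscle in PRINCIPAL_MUSCLES:
                sel = (table.food == food) & (table.side == side) & (table.muscle == muscle)
                if not sel.any():
                    missing.append(f"{food}/{muscle}/{side}")
    if missing:
        raise MetricsError(f"incomplete table; missing cells: {', '.join(missing)}")


def side_asymmetry(table: pd.DataFrame) -> dict[str, float]:
    """Side- and muscle-asymmetry summary statistics.

    Pooled sums are used for the force and contraction deficits; per-case
    means for the stiffness and intrinsic-strength comparisons. These
    conventions match how the published summary percentages pool the
    underlying tables.
    """
    _require_complete(table)
    principal = table[table.muscle.isin(PRINCIPAL_MUSCLES)]
    piv = principal.pivot_table(
        index=["food", "muscle"], columns="side", values=["F_H_N", "dq_C_m"]
    )
    force_deficit = 100.0 * (1.0 - piv["F_H_N"]["N"].sum() / piv["F_H_N"]["W"].sum())
    contraction_deficit = 100.0 * (1.0 - piv["dq_C_m"]["W"].sum() / piv["dq_C_m"]["N"].sum())

    k_piv = table.pivot_table(index=["food", "muscle"], columns="side", values="K_N_per_m")
    stiffness_deficit = float((100.0 * (1.0 - k_piv["N"] / k_piv["W"])).mean())

    ratios = []
    for (muscle, side), grp in table.groupby(["muscle", "side"]):
        g = grp.set_index("food").K_N_per_m
        high = g.reindex(list(_GROUP_HIGH)).mean()
        low = g.reindex(list(_GROUP_LOW)).mean()
        if np.isfinite(high) and np.isfinite(low) and low > 0:
            ratios.append(high / low)
    stiffness_group_ratio = float(np.mean(ratios))

    kk = principal.pivot_table(index=["food", "side"], columns="muscle", values="k_N_per_m2")
    intrinsic_m_vs_mp = float(
        (100.0 * (1.0 - kk["masseter"] / kk["medial_pterygoid"])).mean()
    )
    ff = principal.pivot_table(index=["food", "side"], columns="muscle", values="F_H_N")
    force_mp_vs_m = float((100.0 * (1.0 - ff["medial_pterygoid"] / ff["masseter"])).mean())
    return {
        "force_deficit_pct": float(force_deficit),
        "contraction_deficit_pct": float(contraction_deficit),
        "stiffness_deficit_pct": stiffness_deficit,
        "stiffness_group_ratio": stiffness_group_ratio,
        "intrinsic_masseter_vs_mp_pct": intrinsic_m_vs_mp,
        "force_mp_vs_masseter_pct": force_mp_vs_m,
    }


@dataclass
class StiffnessFunction:
    """Monotone fit of the force-contraction pattern on the rising limb.

    ``force(dq)`` evaluates the fitted F(dq); ``stiffness(dq)`` its
    derivative K(dq) = dF/d(dq). ``K_secant`` is the linear value F_H/dq_H
    and ``rel_gap`` the relative tangent-vs-secant difference at dq_H
    (expected and reported, not an error)."""

    dq: np.ndarray
    F: np.ndarray
    _fit: PchipInterpolator
    K_secant: float
    K_tangent_at_peak: float

    @property
    def rel_gap(self) -> float:
        return abs(self.K_tangent_at_peak - self.K_secant) / self.K_secant

    def force(self, dq):
        return self._fit(np.clip(dq, self.dq[0], self.dq[-1]))

    def stiffness(self, dq):
        return self._fit.derivative()(np.clip(dq, self.dq[0], self.dq[-1]))


def stiffness_fit(dq: np.ndarray, F: np.ndarray, min_samples: int = 20) -> StiffnessFunction:
    """Fit F vs dq on a rising limb (both non-decreasing)."""
    dq = np.asarray(dq, dtype=float)
    F = np.asarray(F, dtype=float)
    if len(dq) < min_samples:
        raise MetricsError(f"need at least {min_samples} rising-limb samples, got {len(dq)}")
    keep = np.concatenate([[True], np.diff(dq) > 1e-12])
    dq, F = dq[keep], F[keep]
    if np.any(np.diff(F) < -1e-9 * max(1.0, float(np.max(np.abs(F))))):
        raise MetricsError("force not monotone on the rising limb")
    F = np.maximum.accumulate(F)  # absorb roundoff wiggles
    fit = PchipInterpolator(dq, F)
    k_sec = float(F[-1] / dq[-1]) if dq[-1] > 0 else np.nan
    k_tan = float(fit.derivative()(dq[-1]))
    return StiffnessFunction(dq=dq, F=F, _fit=fit, K_secant=k_sec, K_tangent_at_peak=k_tan)


def stiffness_function(
    solution: MuscleForceSolution,
    trajectory: MandibleTrajectory,
    muscle: str,
    side: str,
) -> StiffnessFunction:
    """Non-linear stiffness of one muscle from its simulated pattern."""
    series = solution.series(muscle, side)
    q = trajectory.lengths[(muscle, side)]
    i_h = int(np.argmax(series))
    dq = q[0] - q[: i_h + 1]
    return stiffness_fit(dq, series[: i_h + 1])


def comparison_report(computed: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Cell-by-cell comparison of a computed summary against a reference in
    the same schema, with deviations and rounding-aware flags.

    Also recomputes K from the reference's own F_H and dq_H so internal
    inconsistencies of the source tables are surfaced (flag
    ``reference_inconsistent``) instead of being charged to the simulation.
    """
    keys = ["food", "side", "muscle"]
    quantities = {
        "F_H_N": 0.05,  # half of the printed resolution
        "dq_H_m": 0.5e-4,
        "dq_C_m": 0.5e-4,
        "K_N_per_m": 50.0,
        "k_N_per_m2": 500.0,
    }
    merged = computed.merge(reference, on=keys, suffixes=("_sim", "_ref"))
    rows = []
    for r in merged.itertuples():
        for qty, half_unit in quantities.items():
            sim = getattr(r, f"{qty}_sim", np.nan)
            ref = getattr(r, f"{qty}_ref", np.nan)
            if not (np.isfinite(sim) and np.isfinite(ref)):
                continue
            dev = sim - ref
            flags = []
            if qty == "K_N_per_m":
                k_int = getattr(r, "F_H_N_ref") / getattr(r, "dq_H_m_ref")
                if abs(k_int - ref) / ref > 0.05:
                    flags.append("reference_inconsistent")
            rows.append(
                {
                    "food": r.food,
                    "side": r.side,
                    "muscle": r.muscle,
                    "quantity": qty,
                    "computed": sim,
                    "reference": ref,
                    "abs_dev": dev,
                    "pct_dev": 100.0 * dev / ref if ref else np.nan,
                    "within_rounding": abs(dev) <= half_unit,
                    "flags": ";".join(flags),
                }
            )
    return pd.DataFrame(rows)


def report_rounding(table: pd.DataFrame) -> pd.DataFrame:
    """Round a summary table to the precision used in the reference tables:
    forces 0.1 N, contractions 0.1 mm, K 0.1 kN/m, k 0.1 x10^4 N/m^2."""
    out = table.copy()
    if "F_H_N" in out:
        out["F_H_N"] = out["F_H_N"].round(1)
    for col in ("dq_H_m", "dq_C_m"):
        if col in out:
            out[col] = (out[col] * 1e3).round(1) / 1e3
    if "K_N_per_m" in out:
        out["K_N_per_m"] = (out["K_N_per_m"] / 1e3).round(1) * 1e3
    if "k_N_per_m2" in out:
        out["k_N_per_m2"] = (out["k_N_per_m2"] / 1e4).round(1) * 1e4
    return out
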