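"""End-to-end composition of the simulation stages for one food.

Thin plumbing used by the command-line interface, the calibration targets
and the validation checks: food curve -> chewing path -> inverse kinematics
-> force solve -> temporalis split -> metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import chewpath, foodbank, kinematics, kinetostatics, metrics
from .anatomy import AnatomyModel


@dataclass
class FoodRunResult:
    food_id: str
    curve: foodbank.FoodCurve
    path: chewpath.ChewPath
    trajectory: kinematics.MandibleTrajectory
    solution: kinetostatics.MuscleForceSolution
    summary: pd.DataFrame


def run_food(
    model: AnatomyModel,
    food_id: str,
    n_steps: int = 200,
    v_t: float = 0.02,
    curve: foodbank.FoodCurve | None = None,
    mode: str = "validate",
) -> FoodRunResult:
    """Simulate one closing cycle for a catalogued (or custom) food."""
    if curve is None:
        curve = foodbank.default_curve(food_id)
    path = chewpath.make_path(curve.food, v_t=v_t, working_side=model.working_side)
    trajectory = kinematics.run_ik(model, path, n_steps=n_steps)
    solution = kinetostatics.run_forces(model, trajectory, curve, mode=mode)
    summary = metrics.summarize(solution, trajectory, model, food_id)
    return FoodRunResult(
        food_id=food_id,
        curve=curve,
        path=path,
        trajectory=trajectory,
        solution=solution,
        summary=summary,
    )


def run_foods(model: AnatomyModel, food_ids, n_steps: int = 200, v_t: float = 0.02, mode="validate"):
    """Run several foods and return (results dict, concatenated summary)."""
    results = {f: run_food(model, f, n_steps=n_steps, v_t=v_t, mode=mode) for f in food_ids}
    summary = pd.concat([r.summary for r in results.values()], ignore_index=True)
    return results, summary
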