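"""Landmark geometry of the skull-mandible system and its calibration.

The skeleton is reduced to a landmark model: condyle centres, origin and
insertion points of the mandibular elevator muscles (masseter M, medial
pterygoid MP, temporalis T with its anterior/middle/posterior component
lines), the incisal end point IS (coordinate origin), the occlusal load
point IW on the lower first molar of the working side, an occlusal plane,
and one articular guide plane per condyle. The coordinate frame has its
origin at IS with x anterior, y left, z superior, SI metres; the mandible
reference pose is the closed (intercuspal) position.

The masseter and medial pterygoid act through a combined resultant line V
per side; its anchors are convex combinations of the two muscles'
attachments (the combination weights are free, calibrated parameters).

Because the source meshes are not distributable, the default landmark set is
a reconstruction: anatomically plausible starting coordinates tuned by least
squares (``calibrate``) until the full pipeline reproduces published
force-proportionality coefficients and condylar path lengths. The calibrated
values are bundled (``data/default_anatomy.yaml``) so building a default
model involves no optimisation at run time.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field as dc_field
from importlib import resources

import numpy as np
import yaml

PRINCIPAL_MUSCLES = ("masseter", "medial_pterygoid", "temporalis")
TEMPORALIS_PARTS = (
    "temporalis_anterior",
    "temporalis_middle",
    "temporalis_posterior",
)
ALL_LINES = PRINCIPAL_MUSCLES + TEMPORALIS_PARTS + ("V",)
SIDES = ("W", "N")

#: Physiological cross-sectional areas, m^2.
PCSA = {"masseter": 6.80e-4, "medial_pterygoid": 4.37e-4, "temporalis": 8.23e-4}

#: Sagittal-projection angles (degrees from the horizontal sagittal axis) of
#: the temporalis principal vector and its components, the B'C outline edge,
#: and the out-of-sagittal-plane inclinations of the construction lines.
ANGLES_DEG = {
    "alpha": 11.0,
    "phi": 58.0,
    "theta": 76.0,
    "gamma": 42.0,
    "beta": 22.0,
    "delta": 20.0,
    "lambda": 20.0,
}


class AnatomyError(ValueError):
    pass


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise AnatomyError("zero-length direction")
    return v / n


def _plane_normal(slope_deg: float, medial_deg: float, lateral_sign: float) -> np.ndarray:
    """Unit normal of a condylar guide plane.

    ``slope_deg`` tilts the plane about the transverse axis (articular
    eminence slope: forward condyle travel couples to downward travel);
    ``medial_deg`` tilts it about the anteroposterior axis so that forward
    travel also couples to medial drift. ``lateral_sign`` is the sign of the
    condyle's y coordinate.
    """
    sl = math.radians(slope_deg)
    md = math.radians(medial_deg)
    # oriented from the temporal bone into the condyle (downward-ish) so that
    # a non-negative reaction magnitude means joint compression
    n = -np.array([math.sin(sl), -lateral_sign * math.sin(md), math.cos(sl) * math.cos(md)])
    return _unit(n)


@dataclass
class AnatomyModel:
    """Landmark set plus constants; ``working_side`` fixes which anatomical
    side carries the W labels."""

    working_side: str
    landmarks: dict[str, np.ndarray]
    guide_normal_N: np.ndarray
    guide_normal_W: np.ndarray
    occlusal_normal: np.ndarray
    pcsa: dict[str, float] = dc_field(default_factory=lambda: dict(PCSA))
    angles_deg: dict[str, float] = dc_field(default_factory=lambda: dict(ANGLES_DEG))
    params: dict = dc_field(default_factory=dict)  # source parameter set

    # -- basic accessors ---------------------------------------------------
    @property
    def condyle_W(self) -> np.ndarray:
        return self.landmarks["condyle_W"]

    @property
    def condyle_N(self) -> np.ndarray:
        return self.landmarks["condyle_N"]

    @property
    def IS(self) -> np.ndarray:
        return self.landmarks["IS"]

    @property
    def IW(self) -> np.ndarray:
        return self.landmarks["IW"]

    def attachment(self, muscle: str, side: str):
        """(origin, insertion) of a muscle line; origin is skull-fixed,
        insertion mandible-fixed."""
        if muscle not in ALL_LINES or side not in SIDES:
            raise AnatomyError(f"unknown muscle line {muscle!r} side {side!r}")
        return (
            self.landmarks[f"{muscle}_origin_{side}"],
            self.landmarks[f"{muscle}_insertion_{side}"],
        )

    def angles_rad(self) -> dict[str, float]:
        return {k: math.radians(v) for k, v in self.angles_deg.items()}

    # -- pose handling -----------------------------------------------------
    def transform_point(self, p0: np.ndarray, R: np.ndarray) -> np.ndarray:
        """Map a mandible-fixed point through a rotation about the working
        condyle centre."""
        cw = self.condyle_W
        return cw + R @ (p0 - cw)

    def muscle_length(self, muscle: str, side: str, R: np.ndarray | None = None) -> float:
        """Euclidean origin-insertion distance at a pose (identity = closed)."""
        origin, ins = self.attachment(muscle, side)
        if R is not None:
            ins = self.transform_point(ins, R)
        return float(np.linalg.norm(origin - ins))

    def mirrored(self) -> "AnatomyModel":
        """Reflection through the sagittal plane; swaps the working side."""
        flip = np.array([1.0, -1.0, 1.0])
        return AnatomyModel(
            working_side="left" if self.working_side == "right" else "right",
            landmarks={k: v * flip for k, v in self.landmarks.items()},
            guide_normal_N=self.guide_normal_N * flip,
            guide_normal_W=self.guide_normal_W * flip,
            occlusal_normal=self.occlusal_normal * flip,
            pcsa=dict(self.pcsa),
            angles_deg=dict(self.angles_deg),
            params=copy.deepcopy(self.params),
        )


def _build_from_params(params: dict) -> AnatomyModel:
    """Assemble a right-working model from the flat parameter mapping used in
    the bundled YAML (all coordinates are for the working/right side; the
    non-working side is the mirror image)."""
    flip = np.array([1.0, -1.0, 1.0])
    icw = float(params["intercondylar_width"])
    cond = np.array([params["condyle"]["x"], -0.5 * icw, params["condyle"]["z"]])
    lm: dict[str, np.ndarray] = {
        "IS": np.zeros(3),
        "IW": np.asarray(params["iw"], dtype=float),
        "condyle_W": cond,
        "condyle_N": cond * flip,
    }
    for muscle in PRINCIPAL_MUSCLES:
        spec = params[muscle]
        for end in ("origin", "insertion"):
            p = np.asarray(spec[end], dtype=float)
            lm[f"{muscle}_{end}_W"] = p
            lm[f"{muscle}_{end}_N"] = p * flip
    # the anterior/middle/posterior temporalis component lines fan out from
    # the principal insertion (coronoid) at the published sagittal angles
    part_lengths = params["temporalis_parts"]
    ins_t = lm["temporalis_insertion_W"]
    for part, angle_key in (
        ("temporalis_anterior", "theta"),
        ("temporalis_middle", "gamma"),
        ("temporalis_posterior", "beta"),
    ):
        a = math.radians(ANGLES_DEG[angle_key])
        L = float(part_lengths[part.removeprefix("temporalis_") + "_length"])
        origin = ins_t + L * np.array([-math.cos(a), 0.0, math.sin(a)])
        lm[f"{part}_origin_W"] = origin
        lm[f"{part}_origin_N"] = origin * flip
        lm[f"{part}_insertion_W"] = ins_t.copy()
        lm[f"{part}_insertion_N"] = ins_t * flip
    mu_o = float(params["v_weights"]["origin"])
    mu_i = float(params["v_weights"]["insertion"])
    for side in SIDES:
        for end, mu in (("origin", mu_o), ("insertion", mu_i)):
            lm[f"V_{end}_{side}"] = (1.0 - mu) * lm[f"masseter_{end}_{side}"] + mu * lm[
                f"medial_pterygoid_{end}_{side}"
            ]
    gp = params["guide_plane"]
    n_N = _plane_normal(gp["slope_deg"], gp["medial_deg"], lateral_sign=+1.0)
    # the working condyle is seated in the fossa; its contact facet may be
    # oriented differently from the non-working eminence slope
    wp = params.get("working_plane", gp)
    n_W = _plane_normal(wp["slope_deg"], wp["medial_deg"], lateral_sign=-1.0)
    model = AnatomyModel(
        working_side="right",
        landmarks=lm,
        guide_normal_N=n_N,
        guide_normal_W=n_W,
        occlusal_normal=np.array([0.0, 0.0, 1.0]),
        params=copy.deepcopy(params),
    )
    _validate(model)
    return model


def _validate(model: AnatomyModel) -> None:
    if np.allclose(model.condyle_W, model.condyle_N):
        raise AnatomyError("condyle centres coincide")
    for muscle in PRINCIPAL_MUSCLES + TEMPORALIS_PARTS + ("V",):
        for side in SIDES:
            if model.muscle_length(muscle, side) <= 0:
                raise AnatomyError(f"degenerate {muscle} line on side {side}")
    for key in ("guide_normal_N", "guide_normal_W"):
        n = getattr(model, key)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise AnatomyError(f"{key} is not unit length")


def load_params(path=None) -> dict:
    """Load an anatomy parameter mapping (bundled default if no path)."""
    if path is None:
        with resources.files("chewsim.data").joinpath("default_anatomy.yaml").open() as fh:
            return yaml.safe_load(fh)
    with open(path) as fh:
        return yaml.safe_load(fh)


def build_default(working_side: str = "right", params: dict | None = None) -> AnatomyModel:
    """The bundled, pre-calibrated landmark model.

    ``working_side='left'`` returns the mirror image through the sagittal
    plane (the W labels then sit on the left).
    """
    if working_side not in ("right", "left"):
        raise AnatomyError("working_side must be 'right' or 'left'")
    model = _build_from_params(params or load_params())
    return model if working_side == "right" else model.mirrored()


def save_params(params: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

#: Flat addressing of tunable scalars inside the parameter mapping:
#: name -> (path tuple, lower bound, upper bound).
FREE_PARAMETERS = {
    "intercondylar_width": (("intercondylar_width",), 0.05, 0.14),
    "condyle_x": (("condyle", "x"), -0.12, -0.05),
    "condyle_z": (("condyle", "z"), -0.01, 0.05),
    "iw_x": (("iw", 0), -0.08, -0.02),
    "iw_y": (("iw", 1), -0.045, -0.005),
    "guide_slope": (("guide_plane", "slope_deg"), 5.0, 70.0),
    "guide_medial": (("guide_plane", "medial_deg"), -30.0, 30.0),
    "working_slope": (("working_plane", "slope_deg"), -20.0, 70.0),
    "working_medial": (("working_plane", "medial_deg"), -40.0, 40.0),
    "iw_z": (("iw", 2), -0.02, 0.005),
    "v_weight_origin": (("v_weights", "origin"), 0.0, 1.0),
    "v_weight_insertion": (("v_weights", "insertion"), 0.0, 1.0),
}
for _m in PRINCIPAL_MUSCLES:
    for _end in ("origin", "insertion"):
        for _ax, _i in (("x", 0), ("y", 1), ("z", 2)):
            lo, hi = (-0.13, 0.02) if _ax == "x" else ((-0.07, -0.005) if _ax == "y" else (-0.06, 0.12))
            FREE_PARAMETERS[f"{_m}_{_end}_{_ax}"] = ((_m, _end, _i), lo, hi)


def _get(params: dict, path):
    node = params
    for key in path:
        node = node[key]
    return float(node)


def _set(params: dict, path, value: float):
    node = params
    for key in path[:-1]:
        node = node[key]
    node[path[-1]] = float(value)


@dataclass
class CalibrationTarget:
    """One scalar calibration residual: ``evaluate(results)`` maps the
    per-food pipeline results to a value compared against ``target``."""

    name: str
    target: float
    evaluate: callable
    weight: float = 1.0
    tolerance: float = 0.01  # relative


@dataclass
class CalibrationReport:
    tuned: dict[str, float]
    residuals: dict[str, float]  # relative residual per target
    tolerances: dict[str, float]
    converged: bool
    cost: float
    nfev: int = 0

    def summary(self) -> str:
        lines = [f"calibration converged={self.converged} cost={self.cost:.3e}"]
        for name, res in sorted(self.residuals.items()):
            tol = self.tolerances[name]
            mark = "ok " if abs(res) <= tol else "FAIL"
            lines.append(f"  [{mark}] {name}: rel. residual {res:+.4f} (tol {tol:.4f})")
        return "\n".join(lines)


def default_targets() -> list[CalibrationTarget]:
    """The supported target set: published case-I force-proportionality
    coefficients per food and side, the masseter/medial-pterygoid peak-force
    ratio, and the non-working condylar path lengths (the sausage value is
    weighted heavily; the published set is not jointly consistent with a
    height-scaled path family)."""
    from . import fixtures

    targets: list[CalibrationTarget] = []
    rf = fixtures.force_ratios()
    rf = rf[rf["case"] == "I"].set_index(["side", "muscle"]).R_F
    for food in fixtures.FOOD_IDS:
        for side in SIDES:
            for muscle in PRINCIPAL_MUSCLES:
                targets.append(
                    CalibrationTarget(
                        name=f"R_F_{muscle}_{side}_{food}",
                        target=float(rf[(side, muscle)]),
                        evaluate=_ratio_getter(food, muscle, side),
                        weight=2.0,
                        tolerance=0.005,
                    )
                )
    dd = fixtures.condylar_paths().dd_N_m
    for food in fixtures.FOOD_IDS:
        targets.append(
            CalibrationTarget(
                name=f"dd_N_{food}",
                target=float(dd[food]),
                evaluate=lambda res, f=food: res[f]["dd_N"],
                weight=8.0 if food == "s" else 0.3,
                tolerance=0.02 if food == "s" else 0.25,
            )
        )
    return targets


def _ratio_getter(food: str, muscle: str, side: str):
    def get(res):
        r = res[food]
        return r[f"peak_{muscle}_{side}"] / r["F_peak"]

    return get


def _evaluate_model(params: dict, foods, n_steps: int) -> dict:
    """Run the reduced pipeline for each food and collect the quantities the
    calibration targets consume."""
    from . import chewpath, foodbank, kinematics, kinetostatics

    model = _build_from_params(params)
    out = {}
    for food_id in foods:
        curve = foodbank.default_curve(food_id)
        path = chewpath.make_path(curve.food, working_side=model.working_side)
        traj = kinematics.run_ik(model, path, n_steps=n_steps)
        sol = kinetostatics.run_forces(model, traj, curve, mode="exploratory")
        rec = {
            "F_peak": float(np.max(sol.F_food)),
            "dd_N": traj.dd["N"],
            "rq": {
                (m, sd): kinematics.contraction(traj, m, sd) / curve.food.h
                for m in PRINCIPAL_MUSCLES
                for sd in SIDES
            },
            "peak_masseter_W": float(np.max(sol.FM_W)),
            "peak_masseter_N": float(np.max(sol.FM_N)),
            "peak_medial_pterygoid_W": float(np.max(sol.FMP_W)),
            "peak_medial_pterygoid_N": float(np.max(sol.FMP_N)),
            "peak_temporalis_W": float(np.max(sol.FT_W)),
            "peak_temporalis_N": float(np.max(sol.FT_N)),
            "min_force": sol.min_raw_force,
            "min_reaction": float(min(np.min(sol.R_W), np.min(sol.R_N))),
            "max_length_rate": float(traj.max_closing_length_rate()),
        }
        out[food_id] = rec
    return out


def calibrate(
    model: AnatomyModel,
    targets: list[CalibrationTarget] | None = None,
    parameters: list[str] | None = None,
    foods=("d", "b", "a", "c", "s"),
    n_steps: int = 80,
    max_nfev: int = 60,
    feasibility_weight: float = 50.0,
    invariance_weight: float = 2.0,
) -> CalibrationReport:
    """Least-squares tuning of free geometric parameters.

    Residuals are relative deviations from each target, plus hinge penalties
    keeping the model feasible (non-negative muscle forces, compressive
    joint reactions, monotonically shortening elevators during closing) and,
    when several foods are calibrated, soft residuals pulling the per-food
    contraction ratios dq_C/h toward their across-food mean (the
    food-invariance the proportionality analysis relies on; weight
    ``invariance_weight``, 0 disables). The model is updated in place only
    when every named target residual is inside its tolerance; otherwise it
    is left unchanged and the report says so.
    """
    if targets is None:
        targets = default_targets()
    if not targets:
        return CalibrationReport(tuned={}, residuals={}, tolerances={}, converged=True, cost=0.0)
    if parameters is None:
        parameters = list(FREE_PARAMETERS)
    if model.working_side != "right":
        raise AnatomyError("calibrate the canonical right-working model; mirror afterwards")
    from scipy.optimize import least_squares

    params = copy.deepcopy(model.params)
    paths = [FREE_PARAMETERS[p][0] for p in parameters]
    x0 = np.array([_get(params, pth) for pth in paths])
    lo = np.array([FREE_PARAMETERS[p][1] for p in parameters])
    hi = np.array([FREE_PARAMETERS[p][2] for p in parameters])

    def residuals(x):
        trial = copy.deepcopy(params)
        for pth, val in zip(paths, x):
            _set(trial, pth, val)
        n_inv = 6 * len(foods) if (invariance_weight > 0 and len(foods) > 1) else 0
        try:
            res = _evaluate_model(trial, foods, n_steps)
        except Exception:
            return np.full(len(targets) + n_inv + 3, 10.0)
        r = [t.weight * (t.evaluate(res) - t.target) / abs(t.target) for t in targets]
        if invariance_weight > 0 and len(foods) > 1:
            for m in PRINCIPAL_MUSCLES:
                for sd in SIDES:
                    rq = np.array([res[f]["rq"][(m, sd)] for f in foods])
                    r.extend(invariance_weight * (rq - rq.mean()) / rq.mean())
        worst_force = min(rec["min_force"] for rec in res.values())
        worst_react = min(rec["min_reaction"] for rec in res.values())
        worst_rate = max(rec["max_length_rate"] for rec in res.values())
        r.append(feasibility_weight * max(0.0, -worst_force))
        r.append(feasibility_weight * max(0.0, -worst_react))
        r.append(feasibility_weight * max(0.0, worst_rate) * 1e3)
        return np.asarray(r)

    fit = least_squares(
        residuals,
        np.clip(x0, lo, hi),
        bounds=(lo, hi),
        diff_step=1e-3,
        max_nfev=max_nfev,
    )
    trial = copy.deepcopy(params)
    for pth, val in zip(paths, fit.x):
        _set(trial, pth, val)
    res = _evaluate_model(trial, foods, n_steps)
    rel = {t.name: (t.evaluate(res) - t.target) / abs(t.target) for t in targets}
    tol = {t.name: t.tolerance for t in targets}
    converged = all(abs(rel[n]) <= tol[n] for n in rel)
    report = CalibrationReport(
        tuned={p: float(v) for p, v in zip(parameters, fit.x)},
        residuals=rel,
        tolerances=tol,
        converged=converged,
        cost=float(fit.cost),
        nfev=int(fit.nfev),
    )
    if converged:
        new_model = _build_from_params(trial)
        model.landmarks = new_model.landmarks
        model.guide_normal_N = new_model.guide_normal_N
        model.guide_normal_W = new_model.guide_normal_W
        model.params = trial
    return report
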