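"""Inverse kinematics of the mandible along the chewing path.

The mandible is a rigid body with a fixed centre of rotation at the working
condyle (the simulation assumption for unilateral chewing), while the
non-working condyle slides on its articular guide plane. Prescribing the
frontal-plane position of the incisal point along the chewing path closes
the system: each time step solves three rotation unknowns against three
constraints (guide plane, incisal y, incisal z) by a damped Newton iteration
on the rotation group, warm-started from the previous step for continuity.

The solved pose history yields the muscle length series q_j(t) for every
muscle line on both sides (contraction is reported positive for shortening)
and the condylar trajectories, whose polyline length gives the published
path-length measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anatomy import ALL_LINES, SIDES, AnatomyModel
from .chewpath import ChewPath

POSITION_TOL = 1e-10  # m
MAX_NEWTON_ITER = 80


class KinematicsError(RuntimeError):
    pass


def _skew(v):
    return np.array([[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]])


def _rotmat(r: np.ndarray) -> np.ndarray:
    th = np.linalg.norm(r)
    if th < 1e-14:
        return np.eye(3) + _skew(r)
    k = r / th
    K = _skew(k)
    return np.eye(3) + np.sin(th) * K + (1.0 - np.cos(th)) * (K @ K)


def _rotvec(R: np.ndarray) -> np.ndarray:
    cos = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    th = np.arccos(cos)
    if th < 1e-12:
        return np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]]) / 2.0
    axis = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    return th * axis / np.linalg.norm(axis)


@dataclass
class MandiblePose:
    """Pose at one time step: rotation about the working condyle.

    ``opening``/``yaw``/``roll`` are the y/z/x components of the rotation
    vector (rad); ``slide`` is the in-plane displacement of the non-working
    condyle from its closed rest position (m).
    """

    R: np.ndarray
    t: float
    residual: float
    slide: float

    @property
    def rotvec(self) -> np.ndarray:
        return _rotvec(self.R)

    @property
    def opening(self) -> float:
        return float(self.rotvec[1])

    @property
    def yaw(self) -> float:
        return float(self.rotvec[2])

    @property
    def roll(self) -> float:
        return float(self.rotvec[0])


def solve_pose(
    model: AnatomyModel,
    path: ChewPath,
    t: float,
    warm_start: MandiblePose | np.ndarray | None = None,
) -> MandiblePose:
    """Solve the mandible pose whose incisal point sits on the chewing path
    at time ``t`` while the non-working condyle stays on its guide plane."""
    y_t, z_t = path.closing_position(t)
    cw = model.condyle_W
    cn0 = model.condyle_N
    is0 = model.IS
    n_g = model.guide_normal_N
    a_cn0 = cn0 - cw
    a_is0 = is0 - cw
    if warm_start is None:
        R = np.eye(3)
    elif isinstance(warm_start, MandiblePose):
        R = warm_start.R.copy()
    else:
        R = _rotmat(np.asarray(warm_start, dtype=float))
    ey = np.array([0.0, 1.0, 0.0])
    ez = np.array([0.0, 0.0, 1.0])
    for _ in range(MAX_NEWTON_ITER):
        cn = cw + R @ a_cn0
        isp = cw + R @ a_is0
        g = np.array([n_g @ (cn - cn0), isp[1] - y_t, isp[2] - z_t])
        if np.max(np.abs(g)) < POSITION_TOL:
            slide = float(np.linalg.norm(cn - cn0))
            return MandiblePose(R=R, t=float(t), residual=float(np.max(np.abs(g))), slide=slide)
        J = np.vstack(
            [
                np.cross(cn - cw, n_g),
                np.cross(isp - cw, ey),
                np.cross(isp - cw, ez),
            ]
        )
        try:
            delta = np.linalg.solve(J, -g)
        except np.linalg.LinAlgError as exc:
            raise KinematicsError(f"singular kinematic Jacobian at t={t:.4f}s") from exc
        step = np.linalg.norm(delta)
        if step > 0.3:  # damp large corrections far from the solution
            delta *= 0.3 / step
        R = _rotmat(delta) @ R
    raise KinematicsError(
        f"pose iteration did not converge at t={t:.4f}s "
        f"(|residual| = {np.max(np.abs(g)):.3e} m); path point may be unreachable"
    )


@dataclass
class MandibleTrajectory:
    """Pose and muscle-length history over the closing phase."""

    model: AnatomyModel
    path: ChewPath
    t: np.ndarray
    poses: list[MandiblePose] = field(repr=False)
    lengths: dict = field(repr=False)  # (muscle, side) -> q(t) array, m
    condyle_path: dict = field(repr=False)  # side -> (n, 3) array
    dd: dict = field(default_factory=dict)  # side -> polyline length, m

    @property
    def n_steps(self) -> int:
        return len(self.t) - 1

    def q0(self, muscle: str, side: str) -> float:
        """Initial (open-mouth) muscle length."""
        return float(self.lengths[(muscle, side)][0])

    def rotation(self, i: int) -> np.ndarray:
        return self.poses[i].R

    def incisal_point(self, i: int) -> np.ndarray:
        return self.model.transform_point(self.model.IS, self.poses[i].R)

    @property
    def IP(self) -> np.ndarray:
        """Incisal start point: position of the incisor at chewing begin."""
        return self.incisal_point(0)

    def condyle_frame(self) -> pd.DataFrame:
        """Condylar trajectories as a tidy (t, side, x, y, z) table."""
        rows = []
        for side, pts in self.condyle_path.items():
            for t, p in zip(self.t, pts):
                rows.append({"t_s": t, "side": side, "x_m": p[0], "y_m": p[1], "z_m": p[2]})
        return pd.DataFrame(rows)

    def max_closing_length_rate(self) -> float:
        """Largest step-to-step lengthening (m) of the six principal elevator
        lines during closing; the elevators shorten monotonically, so
        positive values flag geometry for which that fails."""
        worst = -np.inf
        for (muscle, side), q in self.lengths.items():
            if muscle not in ("masseter", "medial_pterygoid", "temporalis"):
                continue
            worst = max(worst, float(np.max(np.diff(q))))
        return worst

    def to_frame(self) -> pd.DataFrame:
        cols = {"t_s": self.t}
        rv = np.array([p.rotvec for p in self.poses])
        cols["roll_rad"], cols["opening_rad"], cols["yaw_rad"] = rv[:, 0], rv[:, 1], rv[:, 2]
        cols["slide_m"] = np.array([p.slide for p in self.poses])
        for (muscle, side), q in sorted(self.lengths.items()):
            cols[f"q_{muscle}_{side}_m"] = q
        return pd.DataFrame(cols)


def run_ik(model: AnatomyModel, path: ChewPath, n_steps: int = 200) -> MandibleTrajectory:
    """Solve the inverse task over the closing phase on n_steps+1 grid points.

    Solutions are chained backwards from the closed end position (where the
    identity pose is exact) so every step is warm-started by its neighbour.
    """
    if n_steps < 50:
        raise ValueError("n_steps must be at least 50")
    if (model.working_side == "right") != (path.lateral_sign < 0):
        raise KinematicsError("chewing path and anatomy disagree on the working side")
    t = np.linspace(0.0, path.t_chew, n_steps + 1)
    poses: list[MandiblePose | None] = [None] * (n_steps + 1)
    warm: MandiblePose | None = None
    for i in range(n_steps, -1, -1):
        warm = solve_pose(model, path, t[i], warm_start=warm)
        poses[i] = warm
    lengths = {
        (muscle, side): np.array(
            [model.muscle_length(muscle, side, p.R) for p in poses]
        )
        for muscle in ALL_LINES
        for side in SIDES
    }
    condyle_path = {
        "W": np.array([model.transform_point(model.condyle_W, p.R) for p in poses]),
        "N": np.array([model.transform_point(model.condyle_N, p.R) for p in poses]),
    }
    dd = {
        side: float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        for side, pts in condyle_path.items()
    }
    traj = MandibleTrajectory(
        model=model,
        path=path,
        t=t,
        poses=poses,
        lengths=lengths,
        condyle_path=condyle_path,
        dd=dd,
    )
    # guard against branch jumps of the pose solver (a flip to another root
    # moves muscle lengths by millimetres between neighbouring steps)
    for q in lengths.values():
        if np.max(np.abs(np.diff(q))) > 1e-3 * max(1.0, 200.0 / n_steps):
            raise KinematicsError("muscle length series discontinuous between steps")
    return traj


def contraction(
    trajectory: MandibleTrajectory,
    muscle: str,
    side: str,
    kind: str = "total",
    t_ref: float | None = None,
    solution=None,
) -> float:
    """Muscle contraction dq = q(0) - q(t), positive for shortening.

    kind='total' uses the closed end position; 'at_time' evaluates at
    ``t_ref`` (nearest grid point); 'at_max_force' evaluates where the
    attached force solution for this muscle peaks.
    """
    q = trajectory.lengths[(muscle, side)]
    if kind == "total":
        idx = len(q) - 1
    elif kind == "at_time":
        if t_ref is None:
            raise ValueError("kind='at_time' requires t_ref")
        idx = int(np.argmin(np.abs(trajectory.t - t_ref)))
    elif kind == "at_max_force":
        if solution is None:
            raise ValueError("kind='at_max_force' requires a force solution")
        idx = int(np.argmax(solution.series(muscle, side)))
    else:
        raise ValueError(f"unknown contraction kind {kind!r}")
    return float(q[0] - q[idx])
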