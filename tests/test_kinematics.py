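"""Inverse kinematics: pose solving, constraints, muscle length series."""

import numpy as np
import pytest

import chewsim as cs
from chewsim import kinematics
from chewsim.anatomy import PRINCIPAL_MUSCLES
from chewsim.chewpath import make_path
from chewsim.foodbank import FOOD_IDS, catalog
from chewsim.kinematics import KinematicsError, contraction, run_ik, solve_pose


def test_closed_end_position_is_identity(model):
    path = make_path(catalog("d"))
    pose = solve_pose(model, path, path.t_chew)
    assert np.allclose(pose.R, np.eye(3), atol=1e-9)
    assert pose.slide == pytest.approx(0.0, abs=1e-9)


def test_working_condyle_is_fixed(chocolate_run):
    traj = chocolate_run.trajectory
    cw = traj.model.condyle_W
    assert np.max(np.linalg.norm(traj.condyle_path["W"] - cw, axis=1)) < 1e-12
    assert traj.dd["W"] == pytest.approx(0.0, abs=1e-12)


def test_nonworking_condyle_stays_on_guide_plane(chocolate_run):
    traj = chocolate_run.trajectory
    model = traj.model
    d = (traj.condyle_path["N"] - model.condyle_N) @ model.guide_normal_N
    assert np.max(np.abs(d)) < 1e-9


def test_ik_round_trip_reproduces_path(all_runs):
    for res in all_runs.values():
        traj = res.trajectory
        y, z = traj.path.closing_position(traj.t)
        pts = np.array([traj.incisal_point(i) for i in range(len(traj.t))])
        assert np.max(np.abs(pts[:, 1] - y)) < 1e-9
        assert np.max(np.abs(pts[:, 2] - z)) < 1e-9
        assert max(p.residual for p in traj.poses) < 1e-9


def test_nonworking_condyle_moves_down_forward_medially_during_opening(model):
    """Opening (reverse of closing) drives the non-working condyle downward,
    forward and medially."""
    path = make_path(catalog("s"))
    closed = solve_pose(model, path, path.t_chew)
    open_pose = solve_pose(model, path, 0.0, warm_start=closed)
    cn_closed = model.transform_point(model.condyle_N, closed.R)
    cn_open = model.transform_point(model.condyle_N, open_pose.R)
    delta = cn_open - cn_closed
    assert delta[0] > 0  # forward (+x)
    assert delta[2] < 0  # downward (-z)
    assert abs(cn_open[1]) < abs(cn_closed[1])  # medially (toward midline)


def test_elevators_shorten_monotonically_during_closing(all_runs):
    for res in all_runs.values():
        traj = res.trajectory
        for muscle in PRINCIPAL_MUSCLES:
            for side in ("W", "N"):
                q = traj.lengths[(muscle, side)]
                assert np.all(np.diff(q) <= 1e-9), (res.food_id, muscle, side)


def test_length_series_continuity(chocolate_run):
    traj = chocolate_run.trajectory
    for q in traj.lengths.values():
        assert np.max(np.abs(np.diff(q))) < 1e-4


def test_total_contraction_scales_linearly_with_food_height(all_runs):
    """dq_C / h is food-invariant at fixed geometry (CV < 2%)."""
    for muscle in PRINCIPAL_MUSCLES:
        for side in ("W", "N"):
            ratios = []
            for food_id, res in all_runs.items():
                dq_c = contraction(res.trajectory, muscle, side, kind="total")
                ratios.append(dq_c / catalog(food_id).h)
            ratios = np.array(ratios)
            assert ratios.std() / ratios.mean() < 0.02, (muscle, side)


def test_peak_contraction_fraction_tracks_curve_peak_position(all_runs):
    """The fraction of total contraction reached at the force maximum
    approximates the curve's peak closure fraction p_peak for the V-line
    muscles, whose shortening is nearly proportional to closure."""
    from chewsim.foodbank import DEFAULT_P_PEAK

    for food_id, res in all_runs.items():
        for muscle in ("masseter", "medial_pterygoid"):
            frac = contraction(
                res.trajectory, muscle, "W", kind="at_max_force", solution=res.solution
            ) / contraction(res.trajectory, muscle, "W", kind="total")
            assert frac == pytest.approx(DEFAULT_P_PEAK[food_id], abs=0.06), (
                food_id,
                muscle,
            )


def test_contraction_kinds(chocolate_run):
    traj, sol = chocolate_run.trajectory, chocolate_run.solution
    assert contraction(traj, "masseter", "W", kind="at_time", t_ref=0.0) == 0.0
    total = contraction(traj, "masseter", "W", kind="total")
    at_end = contraction(traj, "masseter", "W", kind="at_time", t_ref=traj.t[-1])
    assert total == at_end
    assert total > 0  # positive = shortening
    at_peak = contraction(traj, "masseter", "W", kind="at_max_force", solution=sol)
    assert 0 < at_peak < total
    with pytest.raises(ValueError, match="force solution"):
        contraction(traj, "masseter", "W", kind="at_max_force")
    with pytest.raises(ValueError, match="unknown contraction kind"):
        contraction(traj, "masseter", "W", kind="bogus")


def test_run_ik_input_validation(model):
    path = make_path(catalog("d"))
    with pytest.raises(ValueError, match="at least 50"):
        run_ik(model, path, n_steps=10)
    left_path = make_path(catalog("d"), working_side="left")
    with pytest.raises(KinematicsError, match="working side"):
        run_ik(model, left_path, n_steps=60)


def test_pose_decomposition_fields(chocolate_run):
    mid = chocolate_run.trajectory.poses[len(chocolate_run.trajectory.poses) // 2]
    # opening about the transverse axis dominates yaw and roll
    assert mid.opening > 0
    assert abs(mid.opening) > abs(mid.yaw)
    assert abs(mid.opening) > abs(mid.roll)
    assert mid.slide > 0


def test_trajectory_frame_export(chocolate_run):
    frame = chocolate_run.trajectory.to_frame()
    assert {"t_s", "opening_rad", "yaw_rad", "roll_rad", "slide_m"} <= set(frame.columns)
    assert "q_masseter_W_m" in frame.columns
    assert len(frame) == len(chocolate_run.trajectory.t)
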