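"""Landmark model, mirroring, muscle lengths and calibration machinery."""

import numpy as np
import pytest

from chewsim import anatomy
from chewsim.anatomy import (
    PCSA,
    AnatomyError,
    CalibrationTarget,
    build_default,
    calibrate,
)
from chewsim.kinematics import _rotmat


def test_default_pcsa_values(model):
    assert model.pcsa["masseter"] == pytest.approx(6.80e-4)
    assert model.pcsa["medial_pterygoid"] == pytest.approx(4.37e-4)
    assert model.pcsa["temporalis"] == pytest.approx(8.23e-4)
    assert PCSA == model.pcsa


def test_published_angles_carried(model):
    rad = model.angles_rad()
    assert model.angles_deg["phi"] == 58.0
    assert rad["theta"] == pytest.approx(np.radians(76.0))
    assert model.angles_deg["delta"] == model.angles_deg["lambda"] == 20.0


def test_load_point_on_working_side(model):
    # right side working: IW sits on the right (y < 0), anterior of the condyle
    assert model.IW[1] < 0
    assert model.IW[0] > model.condyle_W[0]
    left = build_default("left")
    assert left.IW[1] > 0


def test_mirrored_model_is_reflection(model):
    left = model.mirrored()
    assert left.working_side == "left"
    for key, val in model.landmarks.items():
        np.testing.assert_allclose(left.landmarks[key], val * [1, -1, 1])
    np.testing.assert_allclose(left.guide_normal_N, model.guide_normal_N * [1, -1, 1])
    # reflecting twice is the identity
    back = left.mirrored()
    for key, val in model.landmarks.items():
        np.testing.assert_allclose(back.landmarks[key], val)


def test_muscle_length_identity_pose_is_rest_length(model):
    q_closed = model.muscle_length("temporalis", "W")
    assert q_closed == pytest.approx(
        model.muscle_length("temporalis", "W", np.eye(3)), rel=1e-12
    )
    assert q_closed > 0


def test_pure_closing_rotation_shortens_elevators(model):
    """Rotating the mandible open about the transverse condylar axis
    lengthens every elevator line; closing shortens them."""
    R_open = _rotmat(np.array([0.0, 0.12, 0.0]))
    for muscle in ("masseter", "medial_pterygoid", "temporalis"):
        for side in ("W", "N"):
            q_open = model.muscle_length(muscle, side, R_open)
            q_closed = model.muscle_length(muscle, side)
            assert q_open > q_closed, (muscle, side)


def test_mirrored_lengths_equal_under_mirrored_pose(model):
    left = model.mirrored()
    rv = np.array([0.02, 0.1, -0.03])
    rv_mirror = np.array([-0.02, 0.1, 0.03])  # reflection conjugates roll/yaw
    for muscle in ("masseter", "temporalis"):
        for side in ("W", "N"):
            q_r = model.muscle_length(muscle, side, _rotmat(rv))
            q_l = left.muscle_length(muscle, side, _rotmat(rv_mirror))
            assert q_r == pytest.approx(q_l, abs=1e-12)


def test_build_default_validates_side():
    with pytest.raises(AnatomyError):
        build_default("up")


def test_calibrate_empty_targets_is_identity():
    model = build_default("right")
    before = {k: v.copy() for k, v in model.landmarks.items()}
    report = calibrate(model, targets=[])
    assert report.converged
    assert report.residuals == {}
    for key, val in before.items():
        np.testing.assert_allclose(model.landmarks[key], val)


def test_calibrate_requires_canonical_side():
    left = build_default("left")
    with pytest.raises(AnatomyError, match="right-working"):
        calibrate(left, targets=[CalibrationTarget("x", 1.0, lambda r: 1.0)])


def test_calibrate_recovers_perturbed_parameter():
    """Perturbing the intercondylar width changes the non-working condylar
    path length; calibrating against the unperturbed value recovers it."""
    model = build_default("right")
    reference = anatomy._evaluate_model(model.params, ("s",), 60)["s"]["dd_N"]
    import copy

    perturbed = copy.deepcopy(model.params)
    perturbed["intercondylar_width"] *= 1.06
    model_p = build_default("right", params=perturbed)
    target = CalibrationTarget(
        name="dd_N_s",
        target=reference,
        evaluate=lambda res: res["s"]["dd_N"],
        tolerance=0.01,
    )
    report = calibrate(
        model_p,
        targets=[target],
        parameters=["intercondylar_width"],
        foods=("s",),
        n_steps=60,
        max_nfev=15,
    )
    assert report.converged, report.summary()
    assert abs(report.residuals["dd_N_s"]) <= 0.01
    assert model_p.params["intercondylar_width"] == pytest.approx(
        model.params["intercondylar_width"], rel=0.02
    )


def test_calibration_report_summary_format():
    report = anatomy.CalibrationReport(
        tuned={"a": 1.0},
        residuals={"t": 0.002},
        tolerances={"t": 0.01},
        converged=True,
        cost=1e-6,
    )
    text = report.summary()
    assert "converged=True" in text and "ok" in text


def test_temporalis_fan_follows_published_angles(model):
    ins = model.landmarks["temporalis_insertion_W"]
    for part, angle in (
        ("temporalis_anterior", 76.0),
        ("temporalis_middle", 42.0),
        ("temporalis_posterior", 22.0),
    ):
        origin = model.landmarks[f"{part}_origin_W"]
        d = origin - ins
        got = np.degrees(np.arctan2(d[2], -d[0]))
        assert got == pytest.approx(angle, abs=1e-9)
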