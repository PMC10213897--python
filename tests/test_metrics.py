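"""Derived muscle parameters: stiffness, intrinsic strength, ratios,
asymmetry summaries."""

import numpy as np
import pandas as pd
import pytest

from chewsim import fixtures, metrics
from chewsim.foodbank import FOOD_IDS, default_curve
from chewsim.metrics import (
    MetricsError,
    intrinsic_strength,
    proportionality,
    secant_stiffness,
    side_asymmetry,
    stiffness_fit,
)


def test_intrinsic_strength_inversion_is_exact():
    k = intrinsic_strength(233.2, 6.80e-4)
    assert k * 6.80e-4 == 233.2  # exact in floating point
    assert k == pytest.approx(34.3e4, abs=0.05e4)  # masseter working chocolate


def test_secant_stiffness_example():
    K = secant_stiffness(46.1, 3.4e-3)  # temporalis working chocolate
    assert K == pytest.approx(13.6e3, abs=0.05e3)
    with pytest.raises(MetricsError):
        secant_stiffness(10.0, 0.0)


def test_side_asymmetry_reproduces_published_summaries():
    ref = fixtures.reference_metrics_table()
    asym = side_asymmetry(ref)
    assert asym["force_deficit_pct"] == pytest.approx(14.0, abs=0.5)
    assert asym["contraction_deficit_pct"] == pytest.approx(17.0, abs=0.5)
    assert asym["stiffness_deficit_pct"] == pytest.approx(29.0, abs=0.5)
    assert asym["stiffness_group_ratio"] == pytest.approx(2.7, abs=0.05)
    assert asym["intrinsic_masseter_vs_mp_pct"] == pytest.approx(28.0, abs=0.5)
    assert asym["force_mp_vs_masseter_pct"] == pytest.approx(10.0, abs=0.5)


def test_side_asymmetry_zero_for_identical_sides():
    ref = fixtures.reference_metrics_table()
    sym = ref.copy()
    w = sym[sym.side == "W"].drop(columns="side")
    sym = pd.concat(
        [w.assign(side="W"), w.assign(side="N")], ignore_index=True
    )
    asym = side_asymmetry(sym)
    for key in ("force_deficit_pct", "contraction_deficit_pct", "stiffness_deficit_pct",
                "intrinsic_masseter_vs_mp_pct"):
        if key == "intrinsic_masseter_vs_mp_pct":
            continue  # muscle asymmetry is not side asymmetry
        assert asym[key] == pytest.approx(0.0, abs=1e-9)


def test_side_asymmetry_reports_missing_cells():
    ref = fixtures.reference_metrics_table()
    broken = ref[~((ref.food == "d") & (ref.muscle == "masseter") & (ref.side == "N"))]
    with pytest.raises(MetricsError, match="d/masseter/N"):
        side_asymmetry(broken)


def test_proportionality_from_published_tables():
    ref = fixtures.reference_metrics_table()
    principal = ref[ref.muscle.isin(fixtures.PRINCIPAL_MUSCLES)]
    f_max = {f: default_curve(f).F_peak for f in FOOD_IDS}
    table = proportionality(principal, f_max).set_index(["muscle", "side"])
    assert table.loc[("masseter", "W")].R_q == pytest.approx(0.46, abs=0.005)
    assert table.loc[("temporalis", "W")].R_q == pytest.approx(0.74, abs=0.005)
    assert table.loc[("masseter", "N")].R_q == pytest.approx(0.55, abs=0.005)
    # R_F on the published forces against the inverted peak forces is the
    # (documented) circular identity for the masseter
    assert table.loc[("masseter", "W")].R_F == pytest.approx(1.215, rel=1e-3)


def test_proportionality_rejects_bad_f_max():
    ref = fixtures.reference_metrics_table()
    with pytest.raises(MetricsError):
        proportionality(ref, {f: 0.0 for f in FOOD_IDS})


def test_stiffness_fit_linear_quadratic_plateau():
    dq = np.linspace(0.0, 4e-3, 40)
    c = 5.0e4
    lin = stiffness_fit(dq, c * dq)
    assert np.allclose(lin.stiffness(np.linspace(1e-4, 3.9e-3, 7)), c, rtol=1e-9)
    a = 1.0e7
    quad = stiffness_fit(dq, a * dq**2)
    probe = np.linspace(5e-4, 3.5e-3, 7)
    assert np.allclose(quad.stiffness(probe), 2 * a * probe, rtol=0.01)
    flat = stiffness_fit(dq, np.full_like(dq, 3.0))
    assert abs(flat.stiffness(2e-3)) < 1e-6


def test_stiffness_fit_input_validation():
    dq = np.linspace(0.0, 1e-3, 10)
    with pytest.raises(MetricsError, match="at least"):
        stiffness_fit(dq, dq)
    dq = np.linspace(0.0, 1e-3, 30)
    wiggly = np.sin(40 * np.pi * dq / dq[-1])
    with pytest.raises(MetricsError, match="monotone"):
        stiffness_fit(dq, wiggly)


def test_comparison_report_flags_inconsistent_reference_cell():
    ref = fixtures.reference_metrics_table()
    report = metrics.comparison_report(ref, ref)
    cell = report[
        (report.food == "c")
        & (report.side == "W")
        & (report.muscle == "temporalis")
        & (report.quantity == "K_N_per_m")
    ]
    assert cell["flags"].iloc[0] == "reference_inconsistent"
    # self-comparison deviations vanish
    assert np.allclose(report.abs_dev, 0.0)


def test_report_rounding():
    df = pd.DataFrame(
        {"F_H_N": [233.24], "dq_H_m": [0.00213], "dq_C_m": [0.00419],
         "K_N_per_m": [108930.0], "k_N_per_m2": [342941.0]}
    )
    out = metrics.report_rounding(df)
    assert out.F_H_N.iloc[0] == 233.2
    assert out.dq_H_m.iloc[0] == pytest.approx(0.0021)
    assert out.K_N_per_m.iloc[0] == pytest.approx(108900)
    assert out.k_N_per_m2.iloc[0] == pytest.approx(343000)
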