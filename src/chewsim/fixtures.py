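"""Bundled reference tables.

The published per-food muscle summaries (maximum forces, contractions,
stiffness, intrinsic strength, proportionality coefficients and condylar path
lengths) are shipped as plain CSV package data and exposed here as pandas
DataFrames. They serve three purposes: fixture-level arithmetic validation,
calibration targets for the default anatomy, and defaults for the synthetic
food curves.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

FOOD_IDS = ("d", "b", "a", "c", "s")
PRINCIPAL_MUSCLES = ("masseter", "medial_pterygoid", "temporalis")
TEMPORALIS_PARTS = (
    "temporalis_anterior",
    "temporalis_middle",
    "temporalis_posterior",
)
SIDES = ("W", "N")


def _read(name: str) -> pd.DataFrame:
    with resources.files("chewsim.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, comment="#")


@lru_cache(maxsize=None)
def food_catalogue() -> pd.DataFrame:
    """Specimen dimensions (m) and chewing times (s), indexed by food id."""
    return _read("food_catalogue.csv").set_index("id")


@lru_cache(maxsize=None)
def muscle_summary(include_parts: bool = False) -> pd.DataFrame:
    """Maximum force / contraction summary (F_H_N, dq_H_m, dq_C_m) per
    food, side and muscle; optionally including the temporalis components."""
    df = _read("muscle_summary.csv")
    if include_parts:
        df = pd.concat([df, _read("temporalis_parts_summary.csv")], ignore_index=True)
    return df


@lru_cache(maxsize=None)
def stiffness_table() -> pd.DataFrame:
    """Secant stiffness K (N/m) per food, side and muscle."""
    return _read("muscle_stiffness.csv")


@lru_cache(maxsize=None)
def intrinsic_table() -> pd.DataFrame:
    """Intrinsic strength k (N/m^2) per food, side and principal muscle."""
    return _read("intrinsic_strength.csv")


@lru_cache(maxsize=None)
def force_ratios() -> pd.DataFrame:
    """Proportionality coefficients R_F = F_H / F_max per muscle and side."""
    return _read("force_ratios.csv")


@lru_cache(maxsize=None)
def contraction_ratios() -> pd.DataFrame:
    """Proportionality coefficients R_q = dq_C / h per muscle and side."""
    return _read("contraction_ratios.csv")


@lru_cache(maxsize=None)
def condylar_paths() -> pd.DataFrame:
    """Non-working condylar trajectory lengths (m) per food, indexed by id."""
    return _read("condylar_paths.csv").set_index("food")


def force_ratio(muscle: str, side: str) -> float:
    df = force_ratios()
    row = df[(df.muscle == muscle) & (df.side == side)]
    if row.empty:
        raise KeyError(f"no force ratio for muscle={muscle!r} side={side!r}")
    return float(row.R_F.iloc[0])


def reference_metrics_table() -> pd.DataFrame:
    """The published summaries merged into the schema produced by
    :func:`chewsim.metrics.summarize` (one row per food, muscle and side).

    Stiffness and intrinsic strength carry the published values rather than
    being recomputed, so known internal rounding inconsistencies of the
    source tables are preserved (and can be flagged by the comparison
    report). Temporalis components share the principal intrinsic strength.
    """
    df = muscle_summary(include_parts=True).copy()
    stiff = stiffness_table()
    intr = intrinsic_table()
    df = df.merge(stiff, on=["food", "side", "muscle"], how="left")
    df = df.merge(intr, on=["food", "side", "muscle"], how="left")
    temp = intr[intr.muscle == "temporalis"].set_index(["food", "side"]).k_N_per_m2
    part_mask = df.muscle.isin(TEMPORALIS_PARTS)
    df.loc[part_mask, "k_N_per_m2"] = [
        temp[(f, s)] for f, s in zip(df.loc[part_mask, "food"], df.loc[part_mask, "side"])
    ]
    return df
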