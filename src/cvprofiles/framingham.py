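"""Framingham point score (women's categorical system) and mean arterial pressure.

The point score sums integer category points for age, total cholesterol,
HDL-C, blood pressure, smoking and diabetes.  The category table ships as a
versioned JSON data file so tests and implementation share one source; blood
pressure uses the joint SBP x DBP classification where the higher-risk
category governs discordant readings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["age", "total_cholesterol", "hdl", "sbp", "dbp", "smoker"]


@dataclass(frozen=True)
class PointTable:
    """Ordered category boundaries and integer points per risk factor."""

    age_bounds: tuple
    age_points: tuple
    tc_bounds: tuple
    tc_points: tuple
    hdl_bounds: tuple
    hdl_points: tuple
    bp_sbp_bounds: tuple
    bp_dbp_bounds: tuple
    bp_points: tuple
    smoker_points: int
    diabetes_points: int

    def attainable_range(self) -> tuple[int, int]:
        """Exact [min, max] by summing per-factor extremes."""
        lo = (
            min(self.age_points)
            + min(self.tc_points)
            + min(self.hdl_points)
            + min(self.bp_points)
        )
        hi = (
            max(self.age_points)
            + max(self.tc_points)
            + max(self.hdl_points)
            + max(self.bp_points)
            + self.smoker_points
            + self.diabetes_points
        )
        return lo, hi


def load_point_table() -> PointTable:
    raw = json.loads(
        resources.files("cvprofiles.data")
        .joinpath("framingham_points_women.json")
        .read_text()
    )
    return PointTable(
        age_bounds=tuple(raw["age"]["bounds"]),
        age_points=tuple(raw["age"]["points"]),
        tc_bounds=tuple(raw["total_cholesterol"]["bounds"]),
        tc_points=tuple(raw["total_cholesterol"]["points"]),
        hdl_bounds=tuple(raw["hdl"]["bounds"]),
        hdl_points=tuple(raw["hdl"]["points"]),
        bp_sbp_bounds=tuple(raw["blood_pressure"]["sbp_bounds"]),
        bp_dbp_bounds=tuple(raw["blood_pressure"]["dbp_bounds"]),
        bp_points=tuple(raw["blood_pressure"]["points"]),
        smoker_points=int(raw["smoker"]["points"]),
        diabetes_points=int(raw["diabetes"]["points"]),
    )


def mean_arterial_pressure(sbp: float, dbp: float) -> float:
    """MAP = DBP + (SBP - DBP) / 3 (one-third pulse pressure)."""
    sbp = np.asarray(sbp, float)
    dbp = np.asarray(dbp, float)
    if np.any(dbp <= 0) or np.any(sbp < dbp):
        raise ValueError("require sbp >= dbp > 0")
    out = dbp + (sbp - dbp) / 3.0
    return float(out) if out.ndim == 0 else out


def _lookup(value: float, bounds, points, name: str) -> int:
    # bounds has len(points)+1 edges; half-open [lo, hi) categories
    if not (bounds[0] <= value < bounds[-1]):
        raise ValueError(
            f"{name} value {value} outside the point table range "
            f"[{bounds[0]}, {bounds[-1]})"
        )
    idx = int(np.searchsorted(bounds, value, side="right")) - 1
    return int(points[idx])


def framingham_points(
    age: float,
    total_cholesterol: float,
    hdl: float,
    sbp: float,
    dbp: float,
    smoker: int,
    diabetic: int = 0,
    table: PointTable | None = None,
) -> int:
    """Integer point score for one woman; out-of-range inputs raise."""
    if table is None:
        table = load_point_table()
    if age <= 0 or total_cholesterol <= 0 or sbp <= 0 or dbp <= 0:
        raise ValueError("age, cholesterol and pressures must be positive")
    if sbp < dbp:
        raise ValueError("require sbp >= dbp")
    pts = _lookup(age, table.age_bounds, table.age_points, "age")
    pts += _lookup(
        total_cholesterol, table.tc_bounds, table.tc_points, "total_cholesterol"
    )
    pts += _lookup(hdl, table.hdl_bounds, table.hdl_points, "hdl")
    s_cat = _lookup(sbp, table.bp_sbp_bounds, range(5), "sbp")
    d_cat = _lookup(dbp, table.bp_dbp_bounds, range(5), "dbp")
    pts += table.bp_points[max(s_cat, d_cat)]
    pts += table.smoker_points * int(bool(smoker))
    pts += table.diabetes_points * int(bool(diabetic))
    return int(pts)


def fps_column(cohort: pd.DataFrame, table: PointTable | None = None) -> np.ndarray:
    """Vectorized point scores for a cohort table.

    Requires columns age, total_cholesterol, hdl, sbp, dbp, smoker (diabetic
    optional, assumed absent).  A missing required cell raises with the row
    and column named.
    """
    if table is None:
        table = load_point_table()
    for col in REQUIRED_COLUMNS:
        if col not in cohort.columns:
            raise ValueError(f"required column {col!r} absent")
        nulls = cohort[col].isna()
        if nulls.any():
            raise ValueError(
                f"missing value at row {int(nulls.idxmax())}, column {col!r}"
            )
    scores = np.empty(len(cohort), dtype=int)
    diab = cohort["diabetic"] if "diabetic" in cohort.columns else None
    for i, (_, row) in enumerate(cohort.iterrows()):
        scores[i] = framingham_points(
            row["age"],
            row["total_cholesterol"],
            row["hdl"],
            row["sbp"],
            row["dbp"],
            int(row["smoker"]),
            int(diab.iloc[i]) if diab is not None else 0,
            table=table,
        )
    return scores
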