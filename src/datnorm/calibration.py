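"""Phantom cross-calibration of measured SBRs.

Each (scanner, reconstruction condition) pair gets a linear calibration
curve fitted from the phantom series: measured SBR (Y) regressed on the
true SBR from well-counter aliquot concentrations (X).  Harmonization then
applies the inverse map (measured - intercept) / slope to subject SBRs, so
scans from different systems are expressed on the common true-SBR scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CalibrationQualityError,
    DomainError,
    MissingCurveError,
    RankError,
    UnusableCurveError,
)

__all__ = [
    "CalibrationCurve",
    "CalibrationTable",
    "true_sbr_from_aliquots",
    "fit_calibration",
    "apply_calibration",
    "calibrate_cohort",
    "fit_table_from_manifest",
]

#: Default quality gate: phantom fits are near-perfectly linear, so a flat
#: slope or weak correlation signals an acquisition problem.
MIN_SLOPE = 0.1
MIN_R = 0.9


def true_sbr_from_aliquots(striatal_conc: float, background_conc: float) -> float:
    """Ground-truth SBR from aliquot concentrations: striatal/background - 1."""
    if background_conc <= 0:
        raise DomainError(f"background concentration must be > 0, got {background_conc}")
    return striatal_conc / background_conc - 1.0


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear map between true and measured SBR for one scanner/condition.

    ``orientation="measured_on_true"`` (default) stores the regression of
    measured on true, and calibration inverts it; the alternative
    ``"true_on_measured"`` stores the direct true-on-measured fit and
    calibration applies it forward.
    """

    scanner: str
    condition: str
    slope: float
    intercept: float
    r: float
    n_points: int
    orientation: str = "measured_on_true"

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")
        if self.orientation not in ("measured_on_true", "true_on_measured"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.scanner, self.condition)


def fit_calibration(
    true_sbrs,
    measured_sbrs,
    scanner: str,
    condition: str,
    orientation: str = "measured_on_true",
    min_slope: float | None = MIN_SLOPE,
    min_r: float | None = MIN_R,
) -> CalibrationCurve:
    """Least-squares calibration line from a phantom series.

    Fits measured on true by default (the orientation of calibration
    plots); quality gates reject flat or poorly correlated fits (pass
    ``min_slope=None`` / ``min_r=None`` to disable).
    """
    t = np.asarray(true_sbrs, dtype=float)
    m = np.asarray(measured_sbrs, dtype=float)
    if t.shape != m.shape or t.ndim != 1:
        raise ValueError("true and measured SBR lists must be 1-D and equal length")
    if t.size < 2:
        raise ValueError(f"need at least 2 points, got {t.size}")
    if np.ptp(t) == 0:
        raise RankError("all true SBR values identical; calibration line undefined")

    x, y = (t, m) if orientation == "measured_on_true" else (m, t)
    if np.ptp(x) == 0:
        raise RankError("regressor is constant; calibration line undefined")
    res = stats.linregress(x, y)
    r = 1.0 if x.size == 2 else float(res.rvalue)
    curve = CalibrationCurve(
        scanner=scanner,
        condition=condition,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=r,
        n_points=int(t.size),
        orientation=orientation,
    )
    if min_slope is not None and curve.slope <= min_slope:
        raise CalibrationQualityError(
            f"{scanner}/{condition}: slope {curve.slope:.3f} <= {min_slope} fails the quality gate"
        )
    if min_r is not None and abs(curve.r) < min_r:
        raise CalibrationQualityError(
            f"{scanner}/{condition}: |r| {abs(curve.r):.3f} < {min_r} fails the quality gate"
        )
    return curve


def apply_calibration(measured_sbr, curve: CalibrationCurve):
    """Harmonize a measured SBR onto the true-SBR scale.

    For the default orientation this is (measured - b) / a, the inverse of
    the fitted measured-on-true line.  Accepts scalars or arrays.
    """
    if curve.slope <= 0:
        raise UnusableCurveError(
            f"{curve.scanner}/{curve.condition}: slope {curve.slope} <= 0; curve unusable"
        )
    m = np.asarray(measured_sbr, dtype=float)
    if curve.orientation == "measured_on_true":
        out = (m - curve.intercept) / curve.slope
    else:
        out = curve.slope * m + curve.intercept
    return float(out) if np.isscalar(measured_sbr) else out


@dataclass
class CalibrationTable:
    """Collection of calibration curves keyed by (scanner, condition)."""

    curves: dict[tuple[str, str], CalibrationCurve]

    def __post_init__(self) -> None:
        for key, curve in self.curves.items():
            if key != curve.key:
                raise ValueError(f"curve {curve.key} stored under wrong key {key}")

    @classmethod
    def from_curves(cls, curves) -> "CalibrationTable":
        table: dict[tuple[str, str], CalibrationCurve] = {}
        for c in curves:
            if c.key in table:
                raise ValueError(f"duplicate calibration curve for {c.key}")
            table[c.key] = c
        return cls(table)

    def lookup(self, scanner: str, condition: str) -> CalibrationCurve:
        try:
            return self.curves[(scanner, condition)]
        except KeyError:
            raise MissingCurveError(scanner, condition) from None

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "scanner": c.scanner,
                "condition": c.condition,
                "slope": c.slope,
                "intercept": c.intercept,
                "r": c.r,
                "n_points": c.n_points,
                "orientation": c.orientation,
            }
            for c in self.curves.values()
        ]
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationTable":
        payload = json.loads(Path(path).read_text())
        return cls.from_curves(CalibrationCurve(**entry) for entry in payload)


def calibrate_cohort(records, table: CalibrationTable):
    """Fill calibrated left/right SBRs of subject records from the table.

    Accepts a list of SubjectRecord (returns new records; originals kept)
    or a cohort DataFrame (returns a copy with the calibrated columns
    filled).  A record whose (scanner, condition) has no curve raises
    :class:`MissingCurveError` naming the pair.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        cal_r = np.empty(len(df))
        cal_l = np.empty(len(df))
        for i, row in enumerate(df.itertuples(index=False)):
            curve = table.lookup(row.scanner, row.condition)
            cal_r[i] = apply_calibration(row.sbr_right, curve)
            cal_l[i] = apply_calibration(row.sbr_left, curve)
        df["sbr_calibrated_right"] = cal_r
        df["sbr_calibrated_left"] = cal_l
        return df
    out = []
    for rec in records:
        curve = table.lookup(rec.scanner, rec.condition)
        out.append(
            replace(
                rec,
                sbr_calibrated_right=apply_calibration(rec.sbr_right, curve),
                sbr_calibrated_left=apply_calibration(rec.sbr_left, curve),
            )
        )
    return out


def fit_table_from_manifest(
    manifest: pd.DataFrame,
    orientation: str = "measured_on_true",
    min_slope: float | None = MIN_SLOPE,
    min_r: float | None = MIN_R,
) -> CalibrationTable:
    """Fit one curve per (scanner, condition) from a phantom measurement table.

    The manifest needs columns scanner, condition, true_sbr, measured_sbr;
    both hemispheres of each acquisition contribute a point.
    """
    required = {"scanner", "condition", "true_sbr", "measured_sbr"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    curves = []
    for (scanner, condition), g in manifest.groupby(["scanner", "condition"], sort=True):
        curves.append(
            fit_calibration(
                g["true_sbr"].to_numpy(float),
                g["measured_sbr"].to_numpy(float),
                scanner,
                condition,
                orientation=orientation,
                min_slope=min_slope,
                min_r=min_r,
            )
        )
    return CalibrationTable.from_curves(curves)
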