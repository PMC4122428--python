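"""Per-patient linear trend line and the threshold crossing-interval statistic.

The core model: fit ordinary least squares ``HbA1C = b0 + b1 * t`` (t in
days from the index date) to one patient's pre-medication tests, then solve
the fitted line for the days at which it reaches the pre-diabetes (5.7 %)
and diabetes (6.5 %) thresholds.  The crossing interval

    interval_days = t(6.5) - t(5.7) = (6.5 - 5.7) / b1 = 0.8 / b1

is the patient's predicted time to progress across the pre-diabetic band.
Crossing times are pure extrapolation of the line — they may fall before
the index date or after the last observation; that extrapolation is the
model's purpose.  Zero or negative slopes are flagged, never dropped here;
the exclusion policy lives downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort_builder import Thresholds, Trajectory
from .errors import PrediabError


class DegenerateFitError(PrediabError):
    """All observations share one day offset; no slope is identifiable."""


@dataclass(frozen=True)
class TrendLine:
    """OLS fit for one patient: value(t) = intercept + slope * t."""

    patient_id: str
    intercept: float
    slope: float
    n_points: int
    residual_sd: float


@dataclass(frozen=True)
class IntervalEstimate:
    """Crossing times of the two thresholds and their difference in days."""

    patient_id: str
    t_lower: float
    t_upper: float
    interval_days: float
    flag: str  # ok | zero_slope | negative_slope


def fit_trendline(trajectory: Trajectory) -> TrendLine:
    """Closed-form OLS: slope = S_ty / S_tt, intercept = ybar - slope * tbar.

    ``residual_sd`` is sqrt(SSR / (n - 2)) for n > 2 and exactly 0 for the
    two-point fit.
    """
    t = np.asarray(trajectory.days, dtype=float)
    y = np.asarray(trajectory.values, dtype=float)
    n = len(t)
    if n < 2:
        raise ValueError(f"{trajectory.patient_id}: need >=2 points, got {n}")
    tbar = t.mean()
    ybar = y.mean()
    s_tt = float(((t - tbar) ** 2).sum())
    if s_tt == 0.0:
        raise DegenerateFitError(f"{trajectory.patient_id}: all observations on one day")
    slope = float(((t - tbar) * (y - ybar)).sum()) / s_tt
    intercept = ybar - slope * tbar
    resid = y - (intercept + slope * t)
    residual_sd = math.sqrt(float((resid**2).sum()) / (n - 2)) if n > 2 else 0.0
    return TrendLine(trajectory.patient_id, float(intercept), slope, n, residual_sd)


def crossing_time(trendline: TrendLine, level: float) -> float:
    """Day offset at which the fitted line equals ``level``; requires a
    non-zero slope (returns a real number, possibly negative)."""
    if trendline.slope == 0.0:
        raise ZeroDivisionError(f"{trendline.patient_id}: zero slope has no crossing time")
    return (level - trendline.intercept) / trendline.slope


def interval_days(trendline: TrendLine, thresholds: Thresholds = Thresholds()) -> IntervalEstimate:
    """Crossing interval between the two thresholds.

    Never raises: a zero slope yields NaN crossing times with flag
    ``zero_slope``; a negative slope yields the (negative) interval with
    flag ``negative_slope`` so downstream policy can act on it.
    """
    if trendline.slope == 0.0:
        return IntervalEstimate(trendline.patient_id, math.nan, math.nan, math.nan, "zero_slope")
    t_lo = crossing_time(trendline, thresholds.lower)
    t_hi = crossing_time(trendline, thresholds.upper)
    flag = "ok" if trendline.slope > 0 else "negative_slope"
    return IntervalEstimate(trendline.patient_id, t_lo, t_hi, t_hi - t_lo, flag)


def fit_all(trajectories: dict[str, Trajectory], thresholds: Thresholds = Thresholds()):
    """Fit every trajectory; returns (per-patient fit table, degenerate ids).

    The table carries, per patient: intercept, slope, n_points, residual_sd,
    t_lower, t_upper, interval_days and the degeneracy flag.
    """
    import pandas as pd

    rows = []
    degenerate: list[str] = []
    for pid in sorted(trajectories):
        try:
            tl = fit_trendline(trajectories[pid])
        except DegenerateFitError:
            degenerate.append(pid)
            continue
        est = interval_days(tl, thresholds)
        rows.append(
            (pid, tl.intercept, tl.slope, tl.n_points, tl.residual_sd,
             est.t_lower, est.t_upper, est.interval_days, est.flag)
        )
    frame = pd.DataFrame(
        rows,
        columns=["patient_id", "intercept", "slope", "n_points", "residual_sd",
                 "t_lower", "t_upper", "interval_days", "flag"],
    )
    return frame, degenerate
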