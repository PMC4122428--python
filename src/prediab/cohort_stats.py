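"""Trimming, group summaries, ANOVA and the characteristics tables.

The machinery behind the two results tables: symmetric extreme trimming of
the crossing-interval distribution, per-group and pooled mean/SE for the
interval and the medication-delay endpoints, one-way ANOVA across the three
risk groups, day-to-year conversion, and the baseline characteristics table
(age strata, gender, auxiliary lab panel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort_builder import RiskGroup
from .errors import ConfigError

OVERALL = "overall"

#: Age stratum edges in years: <45, 45-59, 60-74, >=75.
AGE_STRATA = ((None, 45), (45, 60), (60, 75), (75, None))


@dataclass
class TrimResult:
    """Symmetric trim of ``ceil(f * n)`` values from each tail."""

    retained: pd.Series  # values indexed by patient_id, sorted ascending
    excluded_low: list[str]
    excluded_high: list[str]
    trim_fraction_per_tail: float

    @property
    def n_excluded_low(self) -> int:
        return len(self.excluded_low)

    @property
    def n_excluded_high(self) -> int:
        return len(self.excluded_high)


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    se: float
    se_defined: bool = True


@dataclass
class AnovaResult:
    variable: str
    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    flag: str = ""


def trim_extremes(intervals: pd.Series, trim_fraction_per_tail: float = 0.025) -> TrimResult:
    """Remove the ``ceil(f*n)`` smallest and largest values (ties broken by
    patient_id, so the trim is deterministic).

    ``ceil`` rather than ``floor`` guarantees any positive fraction trims at
    least one value per tail.  ``f >= 0.5`` (or a trim that would empty the
    sample) is a configuration error.
    """
    if not 0.0 <= trim_fraction_per_tail < 0.5:
        raise ConfigError(
            f"trim_fraction_per_tail: must be in [0, 0.5), got {trim_fraction_per_tail}"
        )
    if intervals.empty:
        raise ValueError("trim_extremes: empty input")
    n = len(intervals)
    # epsilon shields exact products like 0.025 * 40 = 1 from binary round-up
    k = math.ceil(trim_fraction_per_tail * n - 1e-9)
    if 2 * k >= n:
        raise ConfigError(
            f"trim_fraction_per_tail: trimming {2 * k} of {n} values leaves an empty sample"
        )
    df = intervals.rename("value").rename_axis("patient_id").reset_index()
    df = df.sort_values(["value", "patient_id"], kind="stable").reset_index(drop=True)
    low = df.iloc[:k] if k else df.iloc[:0]
    high = df.iloc[n - k:] if k else df.iloc[:0]
    kept = df.iloc[k: n - k]
    retained = kept.set_index("patient_id")["value"]
    return TrimResult(retained, list(low["patient_id"]), list(high["patient_id"]), trim_fraction_per_tail)


def duration_medication(index_date, first_rx_date) -> int:
    """Whole days from index date (first HbA1C) to first prescription."""
    delta = (pd.Timestamp(first_rx_date) - pd.Timestamp(index_date)).days
    if delta < 0:
        raise ValueError("first_rx_date precedes index_date; patient should have been excluded")
    return int(delta)


def _se(values: np.ndarray) -> tuple[float, bool]:
    n = len(values)
    if n < 2:
        return 0.0, False
    return float(np.std(values, ddof=1) / math.sqrt(n)), True


def summarize_groups(values_by_group: dict[str, np.ndarray | list]) -> list[GroupSummary]:
    """Mean and SE (sample SD / sqrt(n)) per group plus the pooled OVERALL
    row computed on the concatenation of all values.  Empty groups are
    reported with n = 0 and NaN mean (and are omitted from any ANOVA)."""
    out = []
    pooled: list[np.ndarray] = []
    for group, vals in values_by_group.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            out.append(GroupSummary(group, 0, math.nan, math.nan, False))
            continue
        se, defined = _se(arr)
        out.append(GroupSummary(group, int(arr.size), float(arr.mean()), se, defined))
        pooled.append(arr)
    allv = np.concatenate(pooled) if pooled else np.array([])
    if allv.size:
        se, defined = _se(allv)
        out.append(GroupSummary(OVERALL, int(allv.size), float(allv.mean()), se, defined))
    else:
        out.append(GroupSummary(OVERALL, 0, math.nan, math.nan, False))
    return out


def pooled_mean(group_means, group_ns) -> float:
    """Size-weighted mean of group means: sum(n_i m_i) / sum(n_i)."""
    means = np.asarray(group_means, dtype=float)
    ns = np.asarray(group_ns, dtype=float)
    if means.shape != ns.shape or means.size == 0 or (ns <= 0).any():
        raise ValueError("pooled_mean: need equal-length, positive inputs")
    return float(np.average(means, weights=ns))


def anova_oneway(groups: list, variable: str = "") -> AnovaResult:
    """Classical one-way ANOVA decomposition.

    F = MSB / MSW with df (k-1, N-k); p is the upper tail of the F
    distribution.  Degenerate inputs: zero between- and within-variance
    gives F = 0, p = 1; zero within-variance with non-zero between gives
    p = 0 with flag ``zero_within_variance``.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    if k < 2:
        raise ValueError("anova_oneway: need at least two groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("anova_oneway: each group needs n >= 2")
    n_total = sum(a.size for a in arrs)
    grand = np.concatenate(arrs).mean()
    ssb = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrs))
    ssw = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    df_b, df_w = k - 1, n_total - k
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(variable, 0.0, 1.0, df_b, df_w, flag="no_variance")
        return AnovaResult(variable, math.inf, 0.0, df_b, df_w, flag="zero_within_variance")
    f_stat = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f_stat, df_b, df_w))
    return AnovaResult(variable, f_stat, p, df_b, df_w)


def days_to_years(days: float, days_per_year: float = 365, decimals: int = 1) -> float:
    """Convert days to years, rounding half up to ``decimals`` places
    (the convention that reproduces the published year figures)."""
    if not np.isfinite(days):
        raise ValueError("days must be finite")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(days) / float(days_per_year))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# characteristics / results tables
# ---------------------------------------------------------------------------

_GROUP_ORDER = [g.value for g in RiskGroup]


def _group_arrays(df: pd.DataFrame, col: str) -> dict[str, np.ndarray]:
    return {
        g: df.loc[df["group"] == g, col].dropna().to_numpy(dtype=float)
        for g in _GROUP_ORDER
    }


def _anova_p(values_by_group: dict[str, np.ndarray], variable: str) -> float:
    eligible = [v for v in values_by_group.values() if v.size >= 2]
    if len(eligible) < 2:
        return math.nan
    return anova_oneway(eligible, variable).p_value


def build_table1(cohort_frame: pd.DataFrame, patients: pd.DataFrame, baseline_labs: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics by risk group (long format).

    Rows: age mean (SD) overall and within the four age strata; gender
    n (%); per auxiliary analyte the measured n (%) and mean (SD) among
    measured.  The p column holds the one-way ANOVA p across groups (for
    gender, ANOVA on the male indicator).
    """
    df = cohort_frame.merge(patients, on="patient_id", how="left")
    df["age"] = (df["index_date"] - df["birth_date"]).dt.days / 365.25
    group_sizes = {g: int((df["group"] == g).sum()) for g in _GROUP_ORDER}

    rows = []

    def add(variable: str, stat: str, per_group: dict[str, float], p: float = math.nan) -> None:
        rows.append({"variable": variable, "stat": stat, **per_group, "p": p})

    ages = _group_arrays(df, "age")
    add("age", "mean", {g: float(a.mean()) if a.size else math.nan for g, a in ages.items()},
        _anova_p(ages, "age"))
    add("age", "sd", {g: float(a.std(ddof=1)) if a.size > 1 else math.nan for g, a in ages.items()})
    for lo, hi in AGE_STRATA:
        name = f"age_{lo or ''}_{hi or ''}"
        sub = df
        if lo is not None:
            sub = sub[sub["age"] >= lo]
        if hi is not None:
            sub = sub[sub["age"] < hi]
        strata = _group_arrays(sub, "age")
        add(name, "mean", {g: float(a.mean()) if a.size else math.nan for g, a in strata.items()})
        add(name, "sd", {g: float(a.std(ddof=1)) if a.size > 1 else math.nan for g, a in strata.items()})

    df["is_male"] = (df["sex"] == "male").astype(float)
    males = _group_arrays(df, "is_male")
    p_gender = _anova_p(males, "gender")
    add("gender_male", "n", {g: float(m.sum()) for g, m in males.items()}, p_gender)
    add("gender_male", "pct",
        {g: 100.0 * m.mean() if m.size else math.nan for g, m in males.items()})
    add("gender_female", "n", {g: float(m.size - m.sum()) for g, m in males.items()})
    add("gender_female", "pct",
        {g: 100.0 * (1.0 - m.mean()) if m.size else math.nan for g, m in males.items()})

    merged = df.merge(baseline_labs, left_on="patient_id", right_index=True, how="left")
    for analyte in baseline_labs.columns:
        vals = _group_arrays(merged, analyte)
        add(analyte, "n_measured", {g: float(v.size) for g, v in vals.items()},
            _anova_p(vals, analyte))
        add(analyte, "pct_measured",
            {g: 100.0 * v.size / group_sizes[g] if group_sizes[g] else math.nan
             for g, v in vals.items()})
        add(analyte, "mean", {g: float(v.mean()) if v.size else math.nan for g, v in vals.items()})
        add(analyte, "sd", {g: float(v.std(ddof=1)) if v.size > 1 else math.nan for g, v in vals.items()})

    return pd.DataFrame(rows, columns=["variable", "stat", *_GROUP_ORDER, "p"])


def build_table2(endpoints: pd.DataFrame) -> pd.DataFrame:
    """Group x endpoint summary (the duration/interval results table).

    ``endpoints`` needs columns patient_id, group, duration_days,
    interval_days (post-trim).  Returns long format: variable, group, n,
    mean, se, p (ANOVA p repeated on each variable's rows).
    """
    rows = []
    for variable in ("duration_days", "interval_days"):
        by_group = _group_arrays(endpoints, variable)
        p = _anova_p(by_group, variable)
        for s in summarize_groups(by_group):
            rows.append(
                {"variable": variable, "group": s.group, "n": s.n,
                 "mean": s.mean, "se": s.se, "p": p}
            )
    return pd.DataFrame(rows, columns=["variable", "group", "n", "mean", "se", "p"])
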