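"""Incident-user cohort construction.

Reproduces the study's exclusion cascade on validated tables:

1. drop patients with any anti-diabetic prescription strictly before their
   first HbA1C test (prevalent users);
2. drop patients with fewer than two distinct HbA1C test dates;
3. keep only patients with an anti-diabetic prescription on/after their
   first HbA1C (the follow-up endpoint), recording the first such date;
4. build each patient's trajectory anchored at the index date (first HbA1C),
   truncated strictly before the first prescription — medication alters the
   trajectory the model extrapolates;
5. assign the risk group from the index HbA1C value and attach baseline
   auxiliary labs from the 3-month window before the index date.

Boundary conventions (configurable): an index value of exactly 5.7 is
increased risk ("low risk" is *less than* 5.7); exactly 6.5 is diabetes,
following the ADA diagnostic criterion HbA1C >= 6.5 %.  A prescription on
the same day as the first HbA1C counts as on/after it (the patient is
retained as an incident user).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from . import reference
from .ehr_io import AUX_ANALYTES, HBA1C, DrugList
from .errors import ConfigError

logger = logging.getLogger(__name__)


class RiskGroup(str, Enum):
    LOW = "low"
    INCREASED = "increased"
    DIABETES = "diabetes"


@dataclass(frozen=True)
class Thresholds:
    """HbA1C band limits in NGSP % (pre-diabetes band is [lower, upper))."""

    lower: float = reference.THRESHOLD_LOWER
    upper: float = reference.THRESHOLD_UPPER

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ConfigError(f"thresholds: lower ({self.lower}) must be < upper ({self.upper})")


@dataclass
class FilterResult:
    """Exhaustive partition of the candidate patient ids."""

    retained: list[str]
    excluded: list[str]
    notes: dict = field(default_factory=dict)


@dataclass
class Trajectory:
    """One patient's pre-medication HbA1C series, anchored at the index date.

    ``days`` are integer offsets from the index date (first HbA1C test),
    strictly increasing, all strictly before the first prescription date;
    same-day duplicate values have been averaged.
    """

    patient_id: str
    index_date: pd.Timestamp
    days: np.ndarray
    values: np.ndarray
    first_rx_date: pd.Timestamp

    @property
    def index_value(self) -> float:
        return float(self.values[0])

    @property
    def n_points(self) -> int:
        return len(self.days)


@dataclass
class ExclusionLedger:
    """Patient bookkeeping: the cascade counts must balance exactly."""

    n_initial: int = 0
    n_prior_medicated: int = 0
    n_single_test: int = 0
    n_no_followup_rx: int = 0
    n_trimmed: int = 0
    n_final: int = 0
    notes: dict = field(default_factory=dict)

    def validate(self) -> "ExclusionLedger":
        counts = [self.n_initial, self.n_prior_medicated, self.n_single_test,
                  self.n_no_followup_rx, self.n_trimmed, self.n_final]
        if any(c < 0 for c in counts):
            raise ValueError(f"ledger counts must be non-negative: {self}")
        expected = (self.n_initial - self.n_prior_medicated - self.n_single_test
                    - self.n_no_followup_rx - self.n_trimmed)
        if self.n_final != expected:
            raise ValueError(f"ledger does not balance: final {self.n_final} != {expected}")
        return self

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": ["initial", "prior_medication", "single_test",
                          "no_followup_rx", "trimmed", "final"],
                "n": [self.n_initial, self.n_prior_medicated, self.n_single_test,
                      self.n_no_followup_rx, self.n_trimmed, self.n_final],
            }
        )


def _hba1c(labs: pd.DataFrame) -> pd.DataFrame:
    return labs[labs["analyte"] == HBA1C]


def _first_hba1c_dates(labs: pd.DataFrame) -> pd.Series:
    return _hba1c(labs).groupby("patient_id")["date"].min()


def _antidiabetic(prescriptions: pd.DataFrame, druglist: DrugList) -> pd.DataFrame:
    return prescriptions[prescriptions["drug_code"].isin(druglist.codes)]


def filter_prior_medication(
    labs: pd.DataFrame, prescriptions: pd.DataFrame, druglist: DrugList
) -> FilterResult:
    """Exclude patients with an anti-diabetic prescription strictly before
    their first HbA1C test (same-day prescriptions retain the patient).

    The candidate universe is every patient with at least one HbA1C record;
    patients holding prescriptions but no HbA1C are noted separately.
    """
    druglist.require_nonempty()
    first_test = _first_hba1c_dates(labs)
    ad = _antidiabetic(prescriptions, druglist)
    first_rx = ad.groupby("patient_id")["date"].min()
    aligned = first_rx.reindex(first_test.index)
    prior = aligned.notna() & (aligned < first_test)
    retained = sorted(first_test.index[~prior])
    excluded = sorted(first_test.index[prior])
    rx_only = sorted(set(ad["patient_id"]) - set(first_test.index))
    if rx_only:
        logger.info("filter_prior_medication: %d patients have prescriptions but no HbA1C", len(rx_only))
    logger.info("filter_prior_medication: retained %d, excluded %d", len(retained), len(excluded))
    return FilterResult(retained, excluded, notes={"rx_without_hba1c": rx_only})


def filter_min_tests(labs: pd.DataFrame, min_tests: int = 2) -> FilterResult:
    """Exclude patients with fewer than ``min_tests`` distinct HbA1C dates
    (several tests on one day count once)."""
    n_dates = _hba1c(labs).groupby("patient_id")["date"].nunique()
    retained = sorted(n_dates.index[n_dates >= min_tests])
    excluded = sorted(n_dates.index[n_dates < min_tests])
    logger.info("filter_min_tests(min=%d): retained %d, excluded %d", min_tests, len(retained), len(excluded))
    return FilterResult(retained, excluded)


def filter_has_followup_rx(
    labs: pd.DataFrame, prescriptions: pd.DataFrame, druglist: DrugList
) -> tuple[FilterResult, pd.Series]:
    """Keep patients with >=1 anti-diabetic prescription on/after their first
    HbA1C date; returns the first such date per retained patient."""
    druglist.require_nonempty()
    first_test = _first_hba1c_dates(labs)
    ft = first_test.rename("first_test").rename_axis("patient_id").reset_index()
    ad = _antidiabetic(prescriptions, druglist).merge(ft, on="patient_id")
    ad = ad[ad["date"] >= ad["first_test"]]
    first_rx = ad.groupby("patient_id")["date"].min()
    retained = sorted(set(first_rx.index) & set(first_test.index))
    excluded = sorted(set(first_test.index) - set(first_rx.index))
    logger.info("filter_has_followup_rx: retained %d, excluded %d", len(retained), len(excluded))
    return FilterResult(retained, excluded), first_rx.loc[retained]


def build_trajectory(patient_labs: pd.DataFrame, first_rx_date: pd.Timestamp) -> Trajectory | None:
    """Build one patient's trajectory, or ``None`` if truncation at the first
    prescription leaves fewer than two points (routed by the caller to the
    single-test exclusion count).

    Index date is the earliest HbA1C date; same-day values are averaged;
    only tests dated strictly before ``first_rx_date`` enter the series.
    The result is independent of input row order.
    """
    a1c = _hba1c(patient_labs)
    if a1c.empty:
        return None
    pid = str(a1c["patient_id"].iloc[0])
    by_day = a1c.groupby("date")["value"].mean().sort_index()
    index_date = by_day.index[0]
    by_day = by_day[by_day.index < first_rx_date]
    if len(by_day) < 2:
        return None
    days = np.array([(d - index_date).days for d in by_day.index], dtype=int)
    return Trajectory(pid, index_date, days, by_day.to_numpy(dtype=float), first_rx_date)


def assign_group(
    index_value: float,
    thresholds: Thresholds = Thresholds(),
    lower_boundary: RiskGroup = RiskGroup.INCREASED,
    upper_boundary: RiskGroup = RiskGroup.DIABETES,
) -> RiskGroup:
    """Map an index HbA1C value to its risk group.

    ``lower_boundary``/``upper_boundary`` choose which side of the band an
    exact threshold value falls on (defaults: 5.7 -> increased risk,
    6.5 -> diabetes).
    """
    if not np.isfinite(index_value):
        raise ValueError(f"index_value must be finite, got {index_value}")
    if index_value < thresholds.lower:
        return RiskGroup.LOW
    if index_value == thresholds.lower:
        return lower_boundary
    if index_value > thresholds.upper:
        return RiskGroup.DIABETES
    if index_value == thresholds.upper:
        return upper_boundary
    return RiskGroup.INCREASED


def attach_baseline_labs(
    labs: pd.DataFrame, index_dates: pd.Series, window_days: int = 90
) -> pd.DataFrame:
    """Baseline auxiliary labs: per patient and analyte, the record dated in
    the closed window ``[index - window_days, index]`` closest to the index
    date (same-day duplicates averaged).  Returns a wide frame indexed by
    patient_id with one column per auxiliary analyte; NaN means unmeasured.
    """
    aux = labs[labs["analyte"].isin(AUX_ANALYTES)].merge(
        index_dates.rename("index_date"), left_on="patient_id", right_index=True
    )
    delta = (aux["index_date"] - aux["date"]).dt.days
    aux = aux[(delta >= 0) & (delta <= window_days)]
    out = pd.DataFrame(index=index_dates.index, columns=list(AUX_ANALYTES), dtype=float)
    out.index.name = "patient_id"
    if not aux.empty:
        day_mean = (
            aux.groupby(["patient_id", "analyte", "date"])["value"].mean().reset_index()
        )
        day_mean["dist"] = (
            day_mean.merge(index_dates.rename("idx"), left_on="patient_id", right_index=True)["idx"]
            - day_mean["date"]
        ).dt.days
        closest = (
            day_mean.sort_values(["patient_id", "analyte", "dist"], kind="stable")
            .groupby(["patient_id", "analyte"])
            .first()["value"]
            .unstack("analyte")
        )
        for col in closest.columns:
            out.loc[closest.index, col] = closest[col]
    return out


@dataclass
class Cohort:
    """Output of the cascade, ready for trend fitting and summaries."""

    frame: pd.DataFrame  # patient_id, index_date, index_value, group, first_rx_date
    trajectories: dict[str, Trajectory]
    baseline_labs: pd.DataFrame
    ledger: ExclusionLedger
    exclusions: pd.DataFrame  # patient_id, reason


def build_cohort(
    labs: pd.DataFrame,
    prescriptions: pd.DataFrame,
    druglist: DrugList,
    thresholds: Thresholds = Thresholds(),
    min_tests: int = 2,
    window_days: int = 90,
    lower_boundary: RiskGroup = RiskGroup.INCREASED,
    upper_boundary: RiskGroup = RiskGroup.DIABETES,
) -> Cohort:
    """Run the full exclusion cascade (steps 1-5; trimming happens later,
    in the statistics stage, because it depends on the fitted intervals)."""
    exclusions: list[tuple[str, str]] = []
    ledger = ExclusionLedger()
    first_test_all = _first_hba1c_dates(labs)
    ledger.n_initial = len(first_test_all)

    prior = filter_prior_medication(labs, prescriptions, druglist)
    ledger.n_prior_medicated = len(prior.excluded)
    ledger.notes["rx_without_hba1c"] = len(prior.notes.get("rx_without_hba1c", []))
    exclusions += [(pid, "PRIOR_MEDICATION") for pid in prior.excluded]
    labs1 = labs[labs["patient_id"].isin(prior.retained)]

    tests = filter_min_tests(labs1, min_tests=min_tests)
    ledger.n_single_test = len(tests.excluded)
    exclusions += [(pid, "SINGLE_TEST") for pid in tests.excluded]
    labs2 = labs1[labs1["patient_id"].isin(tests.retained)]

    followup, first_rx = filter_has_followup_rx(labs2, prescriptions, druglist)
    ledger.n_no_followup_rx = len(followup.excluded)
    exclusions += [(pid, "NO_FOLLOWUP_RX") for pid in followup.excluded]
    labs3 = labs2[labs2["patient_id"].isin(followup.retained)]

    trajectories: dict[str, Trajectory] = {}
    rows = []
    a1c3 = _hba1c(labs3)
    for pid, sub in a1c3.groupby("patient_id"):
        traj = build_trajectory(sub, first_rx.loc[pid])
        if traj is None:
            # <2 pre-prescription points: same deficiency the single-test
            # rule targets, counted there
            ledger.n_single_test += 1
            exclusions.append((pid, "SINGLE_TEST_AFTER_TRUNCATION"))
            continue
        trajectories[pid] = traj
        group = assign_group(traj.index_value, thresholds, lower_boundary, upper_boundary)
        rows.append((pid, traj.index_date, traj.index_value, group.value, traj.first_rx_date))

    frame = pd.DataFrame(
        rows, columns=["patient_id", "index_date", "index_value", "group", "first_rx_date"]
    ).sort_values("patient_id", kind="stable").reset_index(drop=True)
    ledger.n_final = len(frame)  # pre-trim; the stats stage subtracts trims
    ledger.validate()

    baseline = attach_baseline_labs(
        labs, frame.set_index("patient_id")["index_date"], window_days=window_days
    )
    excl_frame = pd.DataFrame(exclusions, columns=["patient_id", "reason"])
    return Cohort(frame, trajectories, baseline, ledger, excl_frame)
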