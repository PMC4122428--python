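"""Exclusion cascade semantics: filters, trajectory construction, grouping,
baseline-lab attachment and ledger conservation."""

import numpy as np
import pandas as pd
import pytest

import prediab as p
from prediab.cohort_builder import RiskGroup, Thresholds

from conftest import make_labs, make_rx

DL = p.DrugList(frozenset({"MET500", "GLI5"}))


class TestPriorMedicationFilter:
    def test_rx_before_first_test_excludes(self):
        labs = make_labs([("P1", "2007-02-01", "HBA1C", 6.0)])
        rx = make_rx([("P1", "2007-01-01", "MET500")])
        res = p.filter_prior_medication(labs, rx, DL)
        assert res.excluded == ["P1"] and res.retained == []

    def test_same_day_rx_retains_incident_user(self):
        labs = make_labs([("P1", "2007-02-01", "HBA1C", 6.0)])
        rx = make_rx([("P1", "2007-02-01", "MET500")])
        assert p.filter_prior_medication(labs, rx, DL).retained == ["P1"]

    def test_non_antidiabetic_rx_is_ignored(self):
        labs = make_labs([("P1", "2007-02-01", "HBA1C", 6.0)])
        rx = make_rx([("P1", "2006-01-01", "ATOR10")])
        assert p.filter_prior_medication(labs, rx, DL).retained == ["P1"]

    def test_five_patient_fixture(self):
        labs = make_labs([(f"P{i}", "2007-03-01", "HBA1C", 6.0) for i in range(1, 6)])
        rx = make_rx([("P1", "2007-01-01", "MET500"), ("P2", "2007-02-15", "GLI5"),
                      ("P3", "2007-04-01", "MET500")])
        res = p.filter_prior_medication(labs, rx, DL)
        assert res.excluded == ["P1", "P2"]
        assert res.retained == ["P3", "P4", "P5"]

    def test_rx_without_hba1c_noted(self):
        labs = make_labs([("P1", "2007-02-01", "HBA1C", 6.0)])
        rx = make_rx([("P9", "2007-01-01", "MET500")])
        res = p.filter_prior_medication(labs, rx, DL)
        assert res.notes["rx_without_hba1c"] == ["P9"]

    def test_empty_druglist_is_config_error(self):
        labs = make_labs([("P1", "2007-02-01", "HBA1C", 6.0)])
        with pytest.raises(p.ConfigError):
            p.filter_prior_medication(labs, make_rx([]), p.DrugList(frozenset()))


class TestMinTestsFilter:
    def test_single_test_excluded(self):
        labs = make_labs([("P1", "2007-01-01", "HBA1C", 6.0)])
        assert p.filter_min_tests(labs).excluded == ["P1"]

    def test_two_tests_same_day_count_once(self):
        labs = make_labs([("P1", "2007-01-01", "HBA1C", 6.0),
                          ("P1", "2007-01-01", "HBA1C", 6.2)])
        assert p.filter_min_tests(labs).excluded == ["P1"]

    def test_ten_patient_fixture(self):
        rows = []
        for i in range(1, 11):
            rows.append((f"P{i:02d}", "2007-01-01", "HBA1C", 6.0))
            if i > 3:  # patients P04..P10 get a second, distinct-date test
                rows.append((f"P{i:02d}", "2007-02-01", "HBA1C", 6.1))
        res = p.filter_min_tests(make_labs(rows))
        assert len(res.retained) == 7 and len(res.excluded) == 3

    def test_non_hba1c_rows_do_not_count(self):
        labs = make_labs([("P1", "2007-01-01", "HBA1C", 6.0),
                          ("P1", "2007-02-01", "CHOL", 190)])
        assert p.filter_min_tests(labs).excluded == ["P1"]


class TestFollowupRxFilter:
    def test_never_prescribed_excluded(self):
        labs = make_labs([("P1", "2007-01-01", "HBA1C", 6.0)])
        res, first_rx = p.filter_has_followup_rx(labs, make_rx([]), DL)
        assert res.excluded == ["P1"] and first_rx.empty

    def test_first_rx_date_is_earliest_on_or_after_index(self):
        labs = make_labs([("P1", "2007-01-01", "HBA1C", 6.0)])
        rx = make_rx([("P1", "2008-05-01", "MET500"), ("P1", "2007-06-01", "GLI5")])
        res, first_rx = p.filter_has_followup_rx(labs, rx, DL)
        assert res.retained == ["P1"]
        assert first_rx.loc["P1"] == pd.Timestamp("2007-06-01")


class TestBuildTrajectory:
    def test_truncation_strictly_before_rx(self):
        labs = make_labs([("P1", "2007-01-01", "HBA1C", 5.8),
                          ("P1", "2007-04-11", "HBA1C", 6.0),   # day 100
                          ("P1", "2007-07-20", "HBA1C", 6.3)])  # day 200
        traj = p.build_trajectory(labs, pd.Timestamp("2007-05-31"))  # day 150
        assert traj.days.tolist() == [0, 100]

    def test_same_day_values_are_averaged(self):
        labs = make_labs([("P1", "2007-01-01", "HBA1C", 6.0),
                          ("P1", "2007-01-01", "HBA1C", 6.2),
                          ("P1", "2007-02-01", "HBA1C", 6.3)])
        traj = p.build_trajectory(labs, pd.Timestamp("2008-01-01"))
        assert traj.index_value == pytest.approx(6.1)

    def test_day_offset_is_calendar_difference(self):
        labs = make_labs([("P1", "2007-01-10", "HBA1C", 6.0),
                          ("P1", "2007-03-01", "HBA1C", 6.1)])
        traj = p.build_trajectory(labs, pd.Timestamp("2009-01-01"))
        assert traj.days.tolist() == [0, 50]

    def test_row_order_does_not_matter(self):
        rows = [("P1", "2007-03-01", "HBA1C", 6.1), ("P1", "2007-01-10", "HBA1C", 6.0)]
        a = p.build_trajectory(make_labs(rows), pd.Timestamp("2009-01-01"))
        b = p.build_trajectory(make_labs(rows[::-1]), pd.Timestamp("2009-01-01"))
        assert a.days.tolist() == b.days.tolist()
        assert a.values.tolist() == b.values.tolist()

    def test_under_two_points_after_truncation_returns_none(self):
        labs = make_labs([("P1", "2007-01-01", "HBA1C", 6.0),
                          ("P1", "2007-06-01", "HBA1C", 6.2)])
        assert p.build_trajectory(labs, pd.Timestamp("2007-03-01")) is None


class TestAssignGroup:
    @pytest.mark.parametrize("value,expected", [
        (5.69, RiskGroup.LOW),
        (5.7, RiskGroup.INCREASED),
        (6.49, RiskGroup.INCREASED),
        (6.5, RiskGroup.DIABETES),
        (6.51, RiskGroup.DIABETES),
        (4.0, RiskGroup.LOW),
    ])
    def test_band_assignment(self, value, expected):
        assert p.assign_group(value) is expected

    def test_boundary_conventions_are_configurable(self):
        assert p.assign_group(5.7, lower_boundary=RiskGroup.LOW) is RiskGroup.LOW
        assert p.assign_group(6.5, upper_boundary=RiskGroup.INCREASED) is RiskGroup.INCREASED

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            p.assign_group(float("nan"))

    def test_partition_is_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(0)
        for v in rng.uniform(3.0, 9.0, 200):
            assert p.assign_group(float(v)) in set(RiskGroup)


class TestBaselineLabs:
    def idx(self):
        return pd.Series({"P1": pd.Timestamp("2007-06-01")})

    def test_outside_window_unmeasured(self):
        labs = make_labs([("P1", "2007-02-21", "CHOL", 190)])  # 100 days before
        out = p.attach_baseline_labs(labs, self.idx(), window_days=90)
        assert np.isnan(out.loc["P1", "CHOL"])

    def test_closest_record_wins(self):
        labs = make_labs([("P1", "2007-03-13", "CREAT", 1.8),   # 80 days before
                          ("P1", "2007-05-22", "CREAT", 1.1)])  # 10 days before
        out = p.attach_baseline_labs(labs, self.idx(), window_days=90)
        assert out.loc["P1", "CREAT"] == 1.1

    def test_index_day_record_counts(self):
        labs = make_labs([("P1", "2007-06-01", "GLU_AC", 120)])
        out = p.attach_baseline_labs(labs, self.idx(), window_days=90)
        assert out.loc["P1", "GLU_AC"] == 120

    def test_measured_count_vector(self):
        labs = make_labs([
            ("P1", "2007-05-01", "CHOL", 190), ("P1", "2007-05-01", "UA", 6.0),
            ("P1", "2007-01-01", "LDL", 110),  # 151 days: outside
        ])
        out = p.attach_baseline_labs(labs, self.idx(), window_days=90)
        assert int(out.loc["P1"].notna().sum()) == 2


class TestLedger:
    def test_balanced_ledger_validates(self):
        led = p.ExclusionLedger(n_initial=49_648, n_prior_medicated=39_762,
                                n_single_test=8_607, n_no_followup_rx=0,
                                n_trimmed=27, n_final=1_252)
        assert led.validate().n_final == 1_252

    def test_unbalanced_ledger_raises(self):
        led = p.ExclusionLedger(n_initial=10, n_prior_medicated=2, n_single_test=1,
                                n_no_followup_rx=0, n_trimmed=0, n_final=8)
        with pytest.raises(ValueError, match="balance"):
            led.validate()

    def test_negative_count_raises(self):
        led = p.ExclusionLedger(n_initial=5, n_prior_medicated=-1, n_single_test=0,
                                n_no_followup_rx=0, n_trimmed=0, n_final=6)
        with pytest.raises(ValueError):
            led.validate()


def test_build_cohort_counts_match_truth(small_tables, small_druglist):
    cohort = p.build_cohort(small_tables.labs, small_tables.prescriptions, small_druglist)
    truth = small_tables.truth
    led = cohort.ledger
    assert led.n_initial == len(truth)
    assert led.n_prior_medicated == (truth["contaminant_class"] == "prior_medicated").sum()
    assert led.n_single_test == (truth["contaminant_class"] == "single_test").sum()
    assert led.n_no_followup_rx == truth["never_triggered"].sum()
    assert led.n_final == len(cohort.frame)
    # group sizes partition the retained cohort
    assert cohort.frame["group"].value_counts().sum() == led.n_final


def test_thresholds_must_be_ordered():
    with pytest.raises(p.ConfigError):
        Thresholds(6.5, 5.7)
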