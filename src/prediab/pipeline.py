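"""End-to-end pipeline: read tables -> cascade -> fits -> trim -> tables.

Deterministic given identical inputs and configuration.  Every excluded
patient id is written exactly once to ``exclusions.csv`` with a
machine-parseable reason code; the exclusion ledger balances by
construction and is re-validated before writing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .cohort_builder import Cohort, RiskGroup, Thresholds, build_cohort
from .cohort_stats import build_table1, build_table2, trim_extremes
from .config import PipelineConfig
from .ehr_io import load_druglist, read_labs, read_patients, read_prescriptions, write_table
from .trendline import fit_all

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    cohort: Cohort
    fits: pd.DataFrame          # all fitted patients (pre-trim)
    endpoints: pd.DataFrame     # retained patients: group, duration, interval
    table1: pd.DataFrame
    table2: pd.DataFrame
    ledger: pd.DataFrame
    exclusions: pd.DataFrame
    diagnostics: dict


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    config.check_inputs()
    thresholds = Thresholds(config.threshold_lower, config.threshold_upper)
    druglist = load_druglist(config.druglist_path).require_nonempty()

    labs_res = read_labs(config.labs_path)
    rx_res = read_prescriptions(config.prescriptions_path)
    pat_res = read_patients(config.patients_path)
    diagnostics = {
        "labs_rejected": len(labs_res.diagnostics),
        "prescriptions_rejected": len(rx_res.diagnostics),
        "patients_rejected": len(pat_res.diagnostics),
    }
    for name, res in (("labs", labs_res), ("prescriptions", rx_res), ("patients", pat_res)):
        if res.diagnostics:
            logger.info("%s: rejected %d rows", name, len(res.diagnostics))

    cohort = build_cohort(
        labs_res.frame,
        rx_res.frame,
        druglist,
        thresholds=thresholds,
        min_tests=config.min_tests,
        window_days=config.window_days,
        lower_boundary=RiskGroup(config.lower_boundary_group),
        upper_boundary=RiskGroup(config.upper_boundary_group),
    )
    ledger = cohort.ledger
    exclusions = [cohort.exclusions]

    fits, degenerate = fit_all(cohort.trajectories, thresholds)
    if degenerate:
        # unidentifiable slope: counts with the single-test deficiency
        ledger.n_single_test += len(degenerate)
        ledger.n_final -= len(degenerate)
        exclusions.append(pd.DataFrame({"patient_id": degenerate, "reason": "DEGENERATE_FIT"}))
        fits = fits[~fits["patient_id"].isin(degenerate)]

    usable = fits
    if config.drop_nonpositive_slopes:
        bad = usable[usable["flag"] != "ok"]
        if len(bad):
            # treated as extreme/degenerate intervals: counted with the trim
            ledger.n_trimmed += len(bad)
            exclusions.append(pd.DataFrame({"patient_id": bad["patient_id"], "reason": "NONPOSITIVE_SLOPE"}))
            usable = usable[usable["flag"] == "ok"]

    merged = usable.merge(cohort.frame, on="patient_id")
    intervals = merged.set_index("patient_id")["interval_days"]

    if config.trim_scope == "pooled":
        trim = trim_extremes(intervals, config.trim_fraction)
        trimmed_low, trimmed_high = trim.excluded_low, trim.excluded_high
        kept_ids = trim.retained.index
    else:
        trimmed_low, trimmed_high, kept = [], [], []
        for _, sub in merged.groupby("group"):
            t = trim_extremes(sub.set_index("patient_id")["interval_days"], config.trim_fraction)
            trimmed_low += t.excluded_low
            trimmed_high += t.excluded_high
            kept.append(t.retained)
        kept_ids = pd.concat(kept).index
    ledger.n_trimmed += len(trimmed_low) + len(trimmed_high)
    exclusions.append(pd.DataFrame({"patient_id": trimmed_low, "reason": "TRIMMED_LOW"}))
    exclusions.append(pd.DataFrame({"patient_id": trimmed_high, "reason": "TRIMMED_HIGH"}))

    final = merged[merged["patient_id"].isin(kept_ids)].copy()
    final["duration_days"] = (final["first_rx_date"] - final["index_date"]).dt.days
    ledger.n_final = len(final)
    ledger.validate()

    endpoints = final[["patient_id", "group", "duration_days", "interval_days"]].reset_index(drop=True)
    table1 = build_table1(
        cohort.frame[cohort.frame["patient_id"].isin(kept_ids)],
        pat_res.frame,
        cohort.baseline_labs.loc[cohort.baseline_labs.index.isin(kept_ids)],
    )
    table2 = build_table2(endpoints)
    excl_frame = pd.concat(exclusions, ignore_index=True).sort_values(
        ["patient_id"], kind="stable").reset_index(drop=True)

    result = PipelineResult(
        cohort=cohort,
        fits=fits.reset_index(drop=True),
        endpoints=endpoints,
        table1=table1,
        table2=table2,
        ledger=ledger.as_frame(),
        exclusions=excl_frame,
        diagnostics=diagnostics,
    )
    if write:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(result.fits, out / "fits.csv")
        write_table(result.endpoints, out / "intervals.csv")
        write_table(result.table1, out / "table1.csv")
        write_table(result.table2, out / "table2.csv")
        write_table(result.ledger, out / "ledger.csv")
        write_table(result.exclusions, out / "exclusions.csv")
        config.to_yaml(out / "effective_config.yaml")
        logger.info("pipeline outputs written to %s", out)
    return result
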