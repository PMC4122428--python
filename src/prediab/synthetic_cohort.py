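"""Synthetic EHR cohort generator.

Emulates the statistical structure the progression analysis assumes, since
the source hospital database is not available:

* three latent risk groups with distinct linear HbA1C slopes — each
  patient's true trajectory is ``value(t) = baseline + slope * t`` sampled
  at irregular visit dates with Gaussian measurement noise;
* an anti-diabetic prescription issued a physician-delay after the first
  visit whose *measured* HbA1C reaches the prescribing trigger (patients
  whose trajectories never reach it inside the study window get no
  prescription and are flagged ``never_triggered`` in the truth table);
* once medication starts, the observed trajectory plateaus (treatment
  suppresses further progression), so only pre-prescription points carry
  the progression signal;
* contaminant patients that must be filtered out downstream: prior
  medication users (anti-diabetic prescription strictly before their first
  HbA1C) and single-test patients (exactly one HbA1C record).

Group and contaminant counts are allocated deterministically by
largest-remainder apportionment, so emitted counts are exactly testable.
All randomness flows from one seeded :class:`numpy.random.Generator`;
identical seed and config give byte-identical tables.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError, model_validator

from . import reference
from .errors import ConfigError
from .ehr_io import AUX_ANALYTES, HBA1C, write_table

#: Invented drug vocabularies (the historical hospital formulary is not
#: published).  Codes in the first tuple are anti-diabetic; the second are
#: unrelated drugs that exercise the "non-anti-diabetic prescriptions are
#: ignored" path.
DEFAULT_ANTIDIABETIC_CODES = ("MET500", "GLI5", "GLM2", "PIO30", "ACA50", "SIT100")
DEFAULT_OTHER_CODES = ("ATOR10", "AMLO5", "ASA100", "OMEP20")

_DEFAULT_DEMOGRAPHICS = (62.7, 13.0, 0.5)  # age mean, age sd, male fraction

_MIN_SLOPE = 1e-6  # %/day; guards 0.8/slope


class GroupProfile(BaseModel):
    """Latent risk group: cohort share and trajectory distribution."""

    label: str
    proportion: float = Field(ge=0.0, le=1.0)
    baseline_mean: float
    baseline_sd: float = Field(ge=0.0)
    slope_mean: float
    slope_sd: float = Field(ge=0.0)


def default_group_profiles() -> list[GroupProfile]:
    """The three published risk groups.

    Proportions reproduce the published group sizes 74/541/637 under
    largest-remainder apportionment of 1,252 clean patients, and slope means
    are ``0.8 / published mean interval`` so the true crossing intervals
    equal the published group means (1169.3 / 1080.5 / 729.4 days).
    Baseline means put each group inside its index-value band.
    """
    n_final = sum(reference.GROUP_N.values())
    baselines = {"low": (5.65, 0.03), "increased": (6.10, 0.12), "diabetes": (6.95, 0.15)}
    profiles = []
    for label in reference.GROUP_LABELS:
        slope = 0.8 / reference.INTERVAL_MEAN_DAYS[label]
        bm, bsd = baselines[label]
        profiles.append(
            GroupProfile(
                label=label,
                proportion=reference.GROUP_N[label] / n_final,
                baseline_mean=bm,
                baseline_sd=bsd,
                slope_mean=slope,
                slope_sd=0.03 * slope,
            )
        )
    return profiles


class SimulationConfig(BaseModel):
    """Full parameterization of one synthetic cohort draw.

    Defaults reproduce the published study conditions: 1,252 clean patients
    split 74/541/637 across risk groups, plus 39,762 prior-medication and
    8,607 single-test contaminants (n_patients = 49,621), HbA1C measurement
    noise 0.1 %, and a study window of 2007-01-01 to 2011-06-30.
    """

    n_patients: int = Field(default=49_621, gt=0)
    group_profiles: list[GroupProfile] = Field(default_factory=default_group_profiles)
    visit_interval_mean: float = Field(default=28.0, gt=0)
    visit_interval_sd: float = Field(default=9.0, ge=0)
    visit_interval_min: float = Field(default=7.0, gt=0)
    entry_day_min: int = Field(default=0, ge=0)
    entry_day_max: int = Field(default=30, ge=0)
    noise_sd: float = Field(default=0.1, ge=0.0)
    prescription_trigger: float = Field(default=reference.THRESHOLD_UPPER)
    prescription_delay_mean: float = Field(default=565.0, gt=0)
    prescription_delay_sd: float = Field(default=140.0, ge=0)
    prescription_delay_min: float = Field(default=300.0, ge=0)
    frac_prior_medicated: float = Field(
        default=reference.CASCADE_PRIOR_MEDICATED / 49_621, ge=0.0, lt=1.0
    )
    frac_single_test: float = Field(default=reference.CASCADE_SINGLE_TEST / 49_621, ge=0.0, lt=1.0)
    study_start: dt.date = dt.date(2007, 1, 1)
    study_end: dt.date = dt.date(2011, 6, 30)
    antidiabetic_codes: tuple[str, ...] = DEFAULT_ANTIDIABETIC_CODES
    other_codes: tuple[str, ...] = DEFAULT_OTHER_CODES
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        total = sum(g.proportion for g in self.group_profiles)
        if not self.group_profiles:
            raise ValueError("group_profiles: at least one group is required")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group_profiles: proportions sum to {total!r}, expected 1")
        if self.frac_prior_medicated + self.frac_single_test >= 1.0:
            raise ValueError("frac_prior_medicated + frac_single_test must be < 1")
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        if self.entry_day_min > self.entry_day_max:
            raise ValueError("entry_day_min must be <= entry_day_max")
        return self


def make_config(**overrides) -> SimulationConfig:
    """Build a :class:`SimulationConfig`, mapping validation failures to
    :class:`ConfigError` with the offending field named."""
    try:
        return SimulationConfig(**overrides)
    except ValidationError as exc:  # re-raise with a compact, named message
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "config"
        raise ConfigError(f"{loc}: {first['msg']}") from exc


@dataclass
class CohortTables:
    """The four generated tables (see ehr_io for schemas)."""

    patients: pd.DataFrame
    labs: pd.DataFrame
    prescriptions: pd.DataFrame
    truth: pd.DataFrame


def largest_remainder(n: int, proportions: Sequence[float]) -> list[int]:
    """Apportion ``n`` into integer counts proportional to ``proportions``.

    Floors the quotas then hands the remaining units to the largest
    fractional remainders (ties to the earlier index).  Exact and
    deterministic; a tiny epsilon shields quotas that are mathematically
    integral from binary round-off.
    """
    if n < 0:
        raise ConfigError("n: must be non-negative")
    quotas = [n * p for p in proportions]
    counts = [math.floor(q + 1e-9) for q in quotas]
    short = n - sum(counts)
    if short < 0:  # epsilon overshoot; trim from smallest remainders
        order = sorted(range(len(quotas)), key=lambda i: (quotas[i] - counts[i], -i))
        for i in order[: -short if short else 0]:
            counts[i] -= 1
    else:
        order = sorted(range(len(quotas)), key=lambda i: (-(quotas[i] - counts[i]), i))
        for i in order[:short]:
            counts[i] += 1
    return counts


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, size: int) -> np.ndarray:
    """Truncated-normal draws (resampling below ``lo``)."""
    if sd == 0:
        return np.full(size, max(mean, lo))
    x = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = x < lo
        if not bad.any():
            break
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.maximum(x, lo)


def _demographics_for(label: str) -> tuple[float, float, float]:
    if label in reference.AGE_MEAN_SD:
        mean, sd = reference.AGE_MEAN_SD[label]
        return mean, sd, reference.MALE_FRACTION[label]
    return _DEFAULT_DEMOGRAPHICS


def generate_cohort(config: SimulationConfig) -> CohortTables:
    """Generate patients, labs, prescriptions and ground-truth tables."""
    if not isinstance(config, SimulationConfig):
        raise ConfigError("config: expected a SimulationConfig")
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp(config.study_start)
    total_days = (config.study_end - config.study_start).days

    n_prior, n_single, n_clean = largest_remainder(
        config.n_patients,
        [config.frac_prior_medicated, config.frac_single_test,
         1.0 - config.frac_prior_medicated - config.frac_single_test],
    )
    group_counts = largest_remainder(n_clean, [g.proportion for g in config.group_profiles])

    width = max(6, len(str(config.n_patients)))
    next_id = 1

    def new_id() -> str:
        nonlocal next_id
        pid = f"P{next_id:0{width}d}"
        next_id += 1
        return pid

    pat_rows: list[tuple] = []
    lab_rows: list[tuple] = []
    rx_rows: list[tuple] = []
    truth_rows: list[tuple] = []

    def add_demographics(pid: str, index_day: int, age_mean: float, age_sd: float, male_frac: float) -> None:
        age = max(21.0, rng.normal(age_mean, age_sd))
        birth = start + pd.Timedelta(days=index_day - round(age * 365.25))
        sex = "male" if rng.random() < male_frac else "female"
        pat_rows.append((pid, sex, birth))

    # ---- clean (non-contaminant) patients -------------------------------
    for profile, n_g in zip(config.group_profiles, group_counts):
        age_mean, age_sd, male_frac = _demographics_for(profile.label)
        for _ in range(n_g):
            pid = new_id()
            baseline = rng.normal(profile.baseline_mean, profile.baseline_sd)
            slope = float(_trunc_normal(rng, profile.slope_mean, profile.slope_sd, _MIN_SLOPE, 1)[0])
            entry = int(rng.integers(config.entry_day_min, config.entry_day_max + 1))
            horizon = total_days - entry
            n_draw = int(horizon / config.visit_interval_min) + 2
            gaps = np.round(
                _trunc_normal(rng, config.visit_interval_mean, config.visit_interval_sd,
                              config.visit_interval_min, n_draw)
            ).astype(int)
            offsets = np.concatenate([[0], np.cumsum(gaps)])
            offsets = offsets[offsets <= horizon]
            noise = rng.normal(0.0, config.noise_sd, len(offsets)) if config.noise_sd > 0 else np.zeros(len(offsets))
            values = baseline + slope * offsets + noise

            hit = np.nonzero(values >= config.prescription_trigger)[0]
            rx_offset: int | None = None
            if len(hit) > 0:
                delay = int(round(_trunc_normal(
                    rng, config.prescription_delay_mean, config.prescription_delay_sd,
                    config.prescription_delay_min, 1)[0]))
                cand = int(offsets[hit[0]]) + delay
                if cand <= horizon:
                    rx_offset = cand
            if rx_offset is not None:
                post = offsets > rx_offset
                values = np.where(post, baseline + slope * rx_offset + noise, values)
                rx_date = start + pd.Timedelta(days=entry + rx_offset)
                rx_rows.append((pid, rx_date, str(rng.choice(config.antidiabetic_codes))))

            for off, val in zip(offsets, values):
                lab_rows.append((pid, start + pd.Timedelta(days=entry + int(off)), HBA1C, float(val), "%"))

            # auxiliary baseline panel, dated 0-120 days before the first
            # HbA1C (clamped to the study window)
            for analyte in AUX_ANALYTES:
                mean, sd, p_measured = reference.AUX_LAB_PANEL[analyte]
                if rng.random() < p_measured:
                    day = max(0, entry - int(rng.integers(0, 121)))
                    val = max(0.05, rng.normal(mean, sd))
                    lab_rows.append((pid, start + pd.Timedelta(days=day), analyte, float(val), "mg/dl"))

            # occasional unrelated prescription (must be ignored by filters)
            if config.other_codes and rng.random() < 0.3:
                off = int(offsets[int(rng.integers(0, len(offsets)))])
                rx_rows.append((pid, start + pd.Timedelta(days=entry + off), str(rng.choice(config.other_codes))))

            add_demographics(pid, entry, age_mean, age_sd, male_frac)
            truth_rows.append((pid, profile.label, slope, 0.8 / slope, "none", rx_offset is None))

    # ---- prior-medication contaminants ----------------------------------
    # contaminants enter a little later so their pre-index prescription
    # history still falls inside the study window
    for _ in range(n_prior):
        pid = new_id()
        entry = int(rng.integers(40, 161))
        rx_day = entry - int(rng.integers(10, 41))
        rx_rows.append((pid, start + pd.Timedelta(days=rx_day), str(rng.choice(config.antidiabetic_codes))))
        n_tests = int(rng.integers(1, 4))
        day = entry
        for _ in range(n_tests):
            lab_rows.append((pid, start + pd.Timedelta(days=day), HBA1C,
                             float(np.clip(rng.normal(7.5, 0.8), 3.0, 18.0)), "%"))
            day += int(rng.integers(60, 121))
        add_demographics(pid, entry, *_DEFAULT_DEMOGRAPHICS)
        truth_rows.append((pid, "", np.nan, np.nan, "prior_medicated", False))

    # ---- single-test contaminants ---------------------------------------
    for _ in range(n_single):
        pid = new_id()
        entry = int(rng.integers(0, 161))
        lab_rows.append((pid, start + pd.Timedelta(days=entry), HBA1C,
                         float(np.clip(rng.normal(6.3, 0.7), 3.0, 18.0)), "%"))
        add_demographics(pid, entry, *_DEFAULT_DEMOGRAPHICS)
        truth_rows.append((pid, "", np.nan, np.nan, "single_test", False))

    patients = pd.DataFrame(pat_rows, columns=["patient_id", "sex", "birth_date"])
    labs = pd.DataFrame(lab_rows, columns=["patient_id", "date", "analyte", "value", "unit"])
    prescriptions = pd.DataFrame(rx_rows, columns=["patient_id", "date", "drug_code"])
    truth = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "group", "true_slope", "true_interval_days",
                 "contaminant_class", "never_triggered"],
    )
    labs = labs.sort_values(["patient_id", "date", "analyte", "value"], kind="stable").reset_index(drop=True)
    prescriptions = prescriptions.sort_values(
        ["patient_id", "date", "drug_code"], kind="stable").reset_index(drop=True)
    patients = patients.sort_values("patient_id", kind="stable").reset_index(drop=True)
    truth = truth.sort_values("patient_id", kind="stable").reset_index(drop=True)
    return CohortTables(patients, labs, prescriptions, truth)


def write_tables(tables: CohortTables, directory: str | Path) -> dict[str, Path]:
    """Write the four tables as CSV into ``directory``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return {
        "patients": write_table(tables.patients, directory / "patients.csv"),
        "labs": write_table(tables.labs, directory / "labs.csv"),
        "prescriptions": write_table(tables.prescriptions, directory / "prescriptions.csv"),
        "truth": write_table(tables.truth, directory / "truth.csv"),
    }
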