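"""Reading, validation and writing of EHR-like delimited tables.

Three input tables drive the pipeline, all CSV with a header row and
ISO-8601 dates:

* ``labs.csv`` — ``patient_id,date,analyte,value,unit``; HbA1C in NGSP %,
  the auxiliary analytes in mg/dl.
* ``prescriptions.csv`` — ``patient_id,date,drug_code``.
* ``patients.csv`` — ``patient_id,sex,birth_date``.

Anti-diabetic status of a drug code is membership in a user-supplied drug
list (one code per line, ``#`` comments allowed): the historical list used
by the source hospitals is not published, so the filter is faithful in form
but data-independent.

Validation never silently drops rows: every input row is either accepted or
reported in the result's ``diagnostics`` with its line number and reason, so
``len(input) == len(accepted) + len(diagnostics)`` always holds.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ConfigError, SchemaError

#: Controlled analyte vocabulary.  HbA1C is the modelled biomarker; the rest
#: form the baseline characteristics panel.
HBA1C = "HBA1C"
AUX_ANALYTES = ("BUN", "CHOL", "CREAT", "GLU_AC", "GOT", "GPT", "HDL", "LDL", "TG", "UA")
ANALYTE_VOCAB = frozenset((HBA1C,) + AUX_ANALYTES)

#: Plausibility guard for HbA1C (NGSP %).  Implementation guard, not a
#: clinical rule; configurable at the read call.
HBA1C_BOUNDS = (2.0, 20.0)

LAB_COLUMNS = ["patient_id", "date", "analyte", "value", "unit"]
PRESCRIPTION_COLUMNS = ["patient_id", "date", "drug_code"]
PATIENT_COLUMNS = ["patient_id", "sex", "birth_date"]
TRUTH_COLUMNS = [
    "patient_id",
    "group",
    "true_slope",
    "true_interval_days",
    "contaminant_class",
    "never_triggered",
]


@dataclass(frozen=True)
class RowDiagnostic:
    """One rejected input row: 1-based data line number, id and reason."""

    line: int
    patient_id: str
    reason: str


@dataclass
class TableReadResult:
    """Accepted rows plus per-row rejection diagnostics."""

    frame: pd.DataFrame
    diagnostics: list[RowDiagnostic] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class DrugList:
    """Set of drug codes considered anti-diabetic."""

    codes: frozenset[str]

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def __len__(self) -> int:
        return len(self.codes)

    def require_nonempty(self) -> "DrugList":
        if not self.codes:
            raise ConfigError("druglist: anti-diabetic filtering requested but the drug list is empty")
        return self


def _read_csv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    return df


def _parse_dates(raw: pd.Series) -> pd.Series:
    return pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")


def read_labs(
    path: str | Path,
    study_window: tuple[dt.date, dt.date] | None = None,
    hba1c_bounds: tuple[float, float] = HBA1C_BOUNDS,
) -> TableReadResult:
    """Read and validate the lab-results table.

    Rows with unparseable dates, non-finite values, HbA1C outside
    ``hba1c_bounds`` (exclusive) or dates outside ``study_window`` (closed)
    are rejected into diagnostics.  Row order is preserved; duplicate
    (patient, date, analyte) rows are retained — de-duplication is a cohort
    construction concern, not an IO concern.
    """
    df = _read_csv(path, LAB_COLUMNS)
    dates = _parse_dates(df["date"])
    values = pd.to_numeric(df["value"], errors="coerce")

    bad = pd.Series("", index=df.index)
    bad[dates.isna()] = "unparseable date"
    finite = values.notna() & ~values.isin([float("inf"), float("-inf")])
    bad[bad.eq("") & ~finite] = "non-numeric or non-finite value"
    is_a1c = df["analyte"].eq(HBA1C)
    lo, hi = hba1c_bounds
    out_of_range = is_a1c & finite & ~values.between(lo, hi, inclusive="neither")
    bad[bad.eq("") & out_of_range] = f"HbA1C value outside plausible range ({lo}, {hi})"
    if study_window is not None:
        start, end = pd.Timestamp(study_window[0]), pd.Timestamp(study_window[1])
        outside = dates.notna() & ~dates.between(start, end)
        bad[bad.eq("") & outside] = "date outside study window"

    diagnostics = [
        RowDiagnostic(line=int(i) + 1, patient_id=str(df.at[i, "patient_id"]), reason=reason)
        for i, reason in bad[bad.ne("")].items()
    ]
    keep = bad.eq("")
    frame = pd.DataFrame(
        {
            "patient_id": df.loc[keep, "patient_id"],
            "date": dates[keep],
            "analyte": df.loc[keep, "analyte"],
            "value": values[keep].astype(float),
            "unit": df.loc[keep, "unit"],
        }
    ).reset_index(drop=True)
    return TableReadResult(frame, diagnostics)


def read_prescriptions(path: str | Path) -> TableReadResult:
    """Read the prescription table; rejects unparseable dates and empty codes."""
    df = _read_csv(path, PRESCRIPTION_COLUMNS)
    dates = _parse_dates(df["date"])
    bad = pd.Series("", index=df.index)
    bad[dates.isna()] = "unparseable date"
    bad[bad.eq("") & df["drug_code"].str.strip().eq("")] = "empty drug_code"
    diagnostics = [
        RowDiagnostic(line=int(i) + 1, patient_id=str(df.at[i, "patient_id"]), reason=reason)
        for i, reason in bad[bad.ne("")].items()
    ]
    keep = bad.eq("")
    frame = pd.DataFrame(
        {
            "patient_id": df.loc[keep, "patient_id"],
            "date": dates[keep],
            "drug_code": df.loc[keep, "drug_code"],
        }
    ).reset_index(drop=True)
    return TableReadResult(frame, diagnostics)


def read_patients(path: str | Path) -> TableReadResult:
    """Read demographics; duplicate patient_ids beyond the first are rejected."""
    df = _read_csv(path, PATIENT_COLUMNS)
    birth = _parse_dates(df["birth_date"])
    sex = df["sex"].str.strip().str.lower()
    sex = sex.where(sex.isin(["male", "female"]), "unknown")
    bad = pd.Series("", index=df.index)
    bad[birth.isna()] = "unparseable birth_date"
    bad[bad.eq("") & df["patient_id"].duplicated(keep="first")] = "duplicate patient_id"
    diagnostics = [
        RowDiagnostic(line=int(i) + 1, patient_id=str(df.at[i, "patient_id"]), reason=reason)
        for i, reason in bad[bad.ne("")].items()
    ]
    keep = bad.eq("")
    frame = pd.DataFrame(
        {
            "patient_id": df.loc[keep, "patient_id"],
            "sex": sex[keep],
            "birth_date": birth[keep],
        }
    ).reset_index(drop=True)
    return TableReadResult(frame, diagnostics)


def read_truth(path: str | Path) -> pd.DataFrame:
    """Read the simulator's ground-truth table (no validation cascade)."""
    df = _read_csv(path, TRUTH_COLUMNS)
    df["true_slope"] = pd.to_numeric(df["true_slope"], errors="coerce")
    df["true_interval_days"] = pd.to_numeric(df["true_interval_days"], errors="coerce")
    df["never_triggered"] = df["never_triggered"].isin(["True", "true", "1"])
    return df


def load_druglist(path: str | Path) -> DrugList:
    """Load anti-diabetic drug codes, one per line; ``#`` starts a comment."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"drug list not found: {path}")
    codes: set[str] = set()
    for raw in path.read_text(encoding="utf-8").splitlines():
        code = raw.split("#", 1)[0].strip()
        if code:
            codes.add(code)
    return DrugList(frozenset(codes))


def write_druglist(druglist: DrugList | frozenset[str] | set[str], path: str | Path) -> Path:
    path = Path(path)
    codes = druglist.codes if isinstance(druglist, DrugList) else frozenset(druglist)
    path.write_text("# anti-diabetic drug codes\n" + "\n".join(sorted(codes)) + "\n", encoding="utf-8")
    return path


def _date_cols(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as UTF-8 CSV with ISO dates; floats round-trip exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _date_cols(df).to_csv(path, index=False)
    return path
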