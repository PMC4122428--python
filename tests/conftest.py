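import pandas as pd
import pytest

import prediab as p


def small_config(**overrides):
    """A fast cohort: 280 patients, contaminants 20%/10%, default groups."""
    base = dict(n_patients=280, frac_prior_medicated=0.2, frac_single_test=0.1, seed=11)
    base.update(overrides)
    return p.make_config(**base)


@pytest.fixture(scope="session")
def small_tables():
    return p.generate_cohort(small_config())


@pytest.fixture(scope="session")
def small_druglist():
    return p.DrugList(frozenset(p.synthetic_cohort.DEFAULT_ANTIDIABETIC_CODES))


@pytest.fixture()
def data_dir(tmp_path, small_tables):
    """small_tables written to disk together with the drug list."""
    from prediab.ehr_io import write_druglist

    d = tmp_path / "data"
    p.write_tables(small_tables, d)
    write_druglist(set(p.synthetic_cohort.DEFAULT_ANTIDIABETIC_CODES), d / "druglist.txt")
    return d


def make_labs(rows):
    """rows: (patient_id, date, analyte, value) -> labs frame."""
    return pd.DataFrame(
        [(pid, pd.Timestamp(date), analyte, float(val), "%") for pid, date, analyte, val in rows],
        columns=["patient_id", "date", "analyte", "value", "unit"],
    )


def make_rx(rows):
    """rows: (patient_id, date, drug_code) -> prescriptions frame."""
    return pd.DataFrame(
        [(pid, pd.Timestamp(date), code) for pid, date, code in rows],
        columns=["patient_id", "date", "drug_code"],
    )
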