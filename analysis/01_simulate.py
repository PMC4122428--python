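#!/usr/bin/env python
"""Generate the default synthetic EHR cohort under results/data/.

The default configuration mirrors the modelled study: 1,252 clean patients
split 74/541/637 across the low-risk / increased-risk / diabetes groups
(true slopes 0.8/1169.3, 0.8/1080.5 and 0.8/729.4 %/day, measurement noise
0.1 %), plus 39,762 prior-medication and 8,607 single-test contaminants for
the exclusion filters to find.
"""

import sys
from pathlib import Path

import prediab as p
from prediab.ehr_io import write_druglist

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    cfg = p.make_config(seed=SEED)
    tables = p.generate_cohort(cfg)
    paths = p.write_tables(tables, OUT)
    paths["druglist"] = write_druglist(set(cfg.antidiabetic_codes), OUT / "druglist.txt")

    truth = tables.truth
    clean = truth[truth["contaminant_class"] == "none"]
    print(f"seed {SEED}: generated {len(truth)} patients "
          f"({len(clean)} clean, {len(truth) - len(clean)} contaminant)")
    print("clean group sizes:", clean["group"].value_counts().to_dict())
    print(f"never triggered in-window (will lack follow-up rx): {int(truth['never_triggered'].sum())}")
    print(f"lab rows: {len(tables.labs)}, prescription rows: {len(tables.prescriptions)}")
    for name, path in paths.items():
        print(f"  wrote {name}: {path}")


if __name__ == "__main__":
    main()
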