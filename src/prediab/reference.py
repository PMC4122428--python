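"""Published summary statistics of the source hospital cohort.

The raw hospital database behind the original progression study is not
publicly available, so these printed group-level summaries serve two roles:

* they parameterize the synthetic cohort generator (group sizes, the slopes
  implied by the published crossing intervals, age/sex structure), and
* they are the *inputs* to the pooled/derived arithmetic that the analysis
  recomputes (weighted overall means, day-to-year conversions, exclusion
  bookkeeping).

All values are exactly as printed in the study's tables; nothing here is a
result computed by this package.
"""

from __future__ import annotations

#: Exclusion cascade of the source cohort (counts of patients).
CASCADE_INITIAL = 49_648
CASCADE_PRIOR_MEDICATED = 39_762
CASCADE_SINGLE_TEST = 8_607
CASCADE_TRIMMED = 27
CASCADE_FINAL = 1_252

#: Final group sizes (low risk / increased risk / diabetes at index).
GROUP_LABELS = ("low", "increased", "diabetes")
GROUP_N = {"low": 74, "increased": 541, "diabetes": 637}

#: Mean crossing interval 5.7% -> 6.5% in days, per group (the study's
#: headline statistic), and the reported overall mean.
INTERVAL_MEAN_DAYS = {"low": 1169.3, "increased": 1080.5, "diabetes": 729.4}
INTERVAL_OVERALL_DAYS = 907.1

#: Mean days from index date (first HbA1C) to first anti-diabetic
#: prescription, per group and overall.
DURATION_MEDICATION_DAYS = {"low": 641.6, "increased": 640.9, "diabetes": 565.7}
DURATION_MEDICATION_OVERALL_DAYS = 602.7

#: Age in years, mean and SD per group, and the male fraction per group.
AGE_MEAN_SD = {
    "low": (61.8, 13.8),
    "increased": (61.92, 12.8),
    "diabetes": (63.41, 13.0),
}
MALE_FRACTION = {"low": 0.649, "increased": 0.486, "diabetes": 0.463}

#: HbA1C risk-band thresholds (NGSP %): below LOWER is low risk, LOWER to
#: UPPER is increased risk (pre-diabetes), at/above UPPER is diabetic.
THRESHOLD_LOWER = 5.7
THRESHOLD_UPPER = 6.5

#: Auxiliary baseline lab panel: analyte code -> (mean, sd, probability a
#: patient has the test within the 3-month baseline window).  Means/SDs are
#: rough overall values from the published characteristics table; the
#: measurement probabilities are the published "n (%)" rates pooled over
#: groups.  Units are mg/dl throughout.
AUX_LAB_PANEL = {
    "BUN": (24.9, 20.0, 0.224),
    "CHOL": (194.5, 47.0, 0.730),
    "CREAT": (1.35, 1.8, 0.712),
    "GLU_AC": (129.0, 33.0, 0.839),
    "GOT": (33.1, 23.0, 0.316),
    "GPT": (35.0, 32.0, 0.648),
    "HDL": (42.9, 12.2, 0.506),
    "LDL": (114.8, 33.8, 0.268),
    "TG": (170.0, 143.0, 0.759),
    "UA": (6.5, 1.6, 0.483),
}
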