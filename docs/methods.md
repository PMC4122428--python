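# Methods

## The model

Each patient contributes an irregular series of HbA1C measurements
(NGSP %). The analysis assumes that, before anti-diabetic treatment
starts, the underlying trajectory is linear in calendar time. For one
patient with tests at day offsets `t_i` (from the index date, the first
HbA1C test) and values `y_i`, we fit ordinary least squares

    y = β₀ + β₁ t,   β₁ = Σ(t−t̄)(y−ȳ) / Σ(t−t̄)²,   β₀ = ȳ − β₁ t̄,

in closed form (no iterative solver). The line is then solved for the two
clinical thresholds: `t(v) = (v − β₀)/β₁`. The crossing interval

    interval = t(6.5) − t(5.7) = 0.8 / β₁   (days)

is a pure extrapolation of the fitted line: it may begin before the index
date and end after the last observation. That is intentional — the
statistic answers "at this patient's fitted rate, how long does the climb
across the pre-diabetic band take", not "what was observed". The fit is
unweighted: the model treats all of a patient's pre-treatment tests as
equally informative and makes no attempt at measurement-error correction,
mixed effects or curvature.

Assumptions worth keeping in mind:

* linearity of the pre-treatment trajectory (medication changes the slope,
  which is why observations on/after the first prescription are excluded);
* measurement noise that is independent between visits;
* a positive slope for the interval to be meaningful. Zero/negative fitted
  slopes are flagged, never silently dropped; by default
  (`drop_nonpositive_slopes: true`) they are excluded before trimming and
  counted with the trimmed patients in the ledger.

## Cohort construction (incident-user design)

The candidate universe is every patient with at least one HbA1C record.
The cascade, in order:

1. **Prior medication** — excluded if any anti-diabetic prescription is
   dated *strictly before* the first HbA1C. A same-day prescription keeps
   the patient: prescribing on the day of the diagnostic test is the
   common clinical pattern, and the incident-user idea is "no exposure
   before follow-up starts", which a same-day prescription does not
   violate. Anti-diabetic status is membership in a user-supplied drug
   list (the historical formulary is not published, so the filter is
   faithful in form but configurable in content).
2. **Minimum tests** — fewer than two *distinct dates* with HbA1C excludes
   the patient; duplicate same-day tests count once.
3. **Follow-up prescription** — the design follows patients to their first
   anti-diabetic prescription; patients never prescribed on/after their
   first test are excluded (no endpoint).
4. **Trajectory** — index date = earliest HbA1C date; same-day duplicates
   averaged (deterministic and order-independent); points on/after the
   first prescription dropped. If fewer than two points survive, the
   patient moves to the minimum-test exclusion count.
5. **Risk group** at the index value: `< 5.7` low, `[5.7, 6.5)` increased,
   `≥ 6.5` diabetes. Exactly 5.7 is *increased* (low risk is defined as
   "less than 5.7"); exactly 6.5 is *diabetes*, following the ADA
   diagnostic criterion. Both boundary conventions are configurable.
6. **Baseline labs** — for each of the ten auxiliary analytes, the record
   inside the closed 90-day window before the index date closest to it
   ("3 months", closest-record-wins; same-day duplicates averaged).

Every excluded patient appears exactly once in `exclusions.csv` with a
machine-parseable reason code, and the ledger identity

    final = initial − prior_medication − single_test − no_followup_rx − trimmed

is validated on every run.

## Trimming and summaries

Crossing intervals have heavy tails (the statistic is a reciprocal of a
noisy slope), so the analysis removes the extreme 2.5 % from each side
before averaging. The rule is `ceil(f·n)` values per tail on the *pooled*
distribution (all groups together), ties broken by patient id. `ceil`
guarantees any positive fraction trims at least one value; per-group
trimming is available by configuration. At the historical scale this
removes 2 × 32 = 64 of 1,279 patients — the historical count of 27 total
cannot be produced by any symmetric 2.5 % percentile rule, so the fraction
is configurable and the ledger records what actually ran.

Group summaries report the arithmetic mean and SE = sample SD (n−1
denominator) / √n; the overall row is computed on the concatenation, which
equals the size-weighted pooling of group means. Group comparisons use
classical one-way ANOVA (F = MSB/MSW, p from the upper F tail; for the
gender row the ANOVA runs on the male indicator). Degenerate inputs:
all-equal data gives F = 0, p = 1; zero within-group variance with
distinct means reports p = 0 with a flag. Day→year conversions divide by
365 and round half-up; this reproduces the published 3.2, 2.96 and 2.49
year figures (the published 1.99 for the diabetes group is not reproducible
under any single consistent rounding rule and is treated as a source
inconsistency).

## The synthetic cohort

The source hospital database is unavailable, so a seeded generator
emulates its structure. Clean patients follow
`value(t) = baseline + slope·t + ε`, `ε ~ N(0, 0.1 %)`, sampled at visits
whose gaps are truncated-normal (mean 28 d, SD 9 d, minimum 7 d — roughly
monthly monitoring of an at-risk population). Group parameters:

| group | share | baseline (mean ± SD, %) | slope mean (%/day) | true interval (d) |
|---|---|---|---|---|
| low | 74/1252 | 5.65 ± 0.03 | 0.8/1169.3 | 1169.3 |
| increased | 541/1252 | 6.10 ± 0.12 | 0.8/1080.5 | 1080.5 |
| diabetes | 637/1252 | 6.95 ± 0.15 | 0.8/729.4 | 729.4 |

Slope SD is 3 % of each group mean. Counts are apportioned by largest
remainder, so the default emits exactly 74/541/637 clean patients plus
39,762 prior-medication and 8,607 single-test contaminants. A prescription
is issued a physician-delay (truncated normal, mean 565 d, SD 140 d,
minimum 300 d — anchored to the published diabetes-group medication delay
of 565.7 d) after the first visit whose *measured* value reaches the
trigger (default 6.5 %); afterwards the observed trajectory plateaus, so
post-prescription tests carry no progression signal and exercise the
truncation rule. Patients whose trajectories never reach the trigger
inside the window receive no prescription, are flagged in the truth table,
and fall to the follow-up filter — with the published slopes a low-risk
patient needs ≈ 1,250 days just to reach 6.5 %, so a 4.5-year window
cannot deliver a prescription to every slow progressor under any realistic
delay; the handful of retained low-risk patients mirrors why the source
cohort's low-risk group is its smallest by far. The delay floor also
guarantees every retained patient at least ~10 pre-prescription visits, so
slope estimates are stable enough for the reciprocal statistic.

Demographics (group-specific age means/SDs, male fractions) and the
auxiliary lab panel (measurement probabilities, means, SDs) are drawn from
the published characteristics table; auxiliary labs are dated 0–120 days
before the first HbA1C (clamped to the window), so some fall outside the
90-day baseline window on purpose. All randomness flows from a single
`numpy.random.Generator(seed)`; equal seed and config give byte-identical
CSV output.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: non-linear or treatment-responsive HbA1C
dynamics before prescription, visit frequency that depends on disease
severity, dosing/adherence, comorbidity structure beyond independent lab
draws, calendar seasonality, or the medication-delay distributions of the
slow groups (a single delay distribution cannot reproduce the published
~641-day delays for low/increased risk *and* keep those patients inside
the window; the generator favours window feasibility, so simulated delays
for slow groups are much longer than the published ones and are not an
acceptance quantity).

## Numerical conventions

* OLS in centered closed form (numerically stable for day offsets in the
  thousands); validated against an exact rational-arithmetic solve of the
  normal equations to 1e-10.
* `ceil` computations on fraction×count subtract 1e-9 before ceiling so
  binary representation error cannot inflate an exact product.
* HbA1C plausibility bounds (2–20 %) at ingestion are an implementation
  guard, configurable, with per-row diagnostics; validation never silently
  drops rows (`accepted + rejected = input`).
* SE of a single value is reported as 0 with an explicit
  `se_defined=False` flag.
* Dates are calendar dates; day offsets are whole days.

## Problem sizes

The default simulation (49,621 patients, ≈ 170k lab rows) generates and
analyses in well under a minute on one core; the test suite uses a
280-patient configuration for most end-to-end checks and the full default
scale for the parameter-recovery acceptance checks.

## Known limitations

* The trend line is descriptive, not causal; no confidence intervals are
  produced for crossing times.
* Group assignment uses the noisy measured index value, as the original
  design did; patients near a threshold can be mis-binned, which slightly
  mixes adjacent groups' slopes.
* The trimmed mean of a reciprocal statistic retains a small positive
  bias for the steepest group (shortest follow-up span); at the default
  scale this is ≈ +3 % and inside the acceptance band.
* A single pooled trim interacts with group structure: the slowest group
  loses disproportionately many members to the upper tail when its n is
  small.
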