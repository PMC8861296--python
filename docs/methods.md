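# Methods

This note documents the models, conventions and design choices behind
`vancodose`: what each stage assumes, which knobs matter, what the
synthetic cohort does and does not emulate, and where the genuinely open
decisions were made.

## Label derivation

The label is the *target daily dose*: the daily dose believed to put the
patient's trough into the therapeutic window (default [14, 20] mcg/mL,
inclusive at both ends) at the time of the record.

**Daily-dose aggregation.**  An administration anchors a record.  Its daily
dose is the sum of doses over the 20 h ending at (and including) the
anchor, excluding any dose more than 30 h before the matched trough.  The
two cut-offs use different anchors deliberately — the 20 h window keys on
the injection, the 30 h cut-off on the trough — which is the reading that
reproduces the published worked examples.  An anchor more than 30 h before
its trough yields an empty window and the record is excluded.

**Trough matching.**  A trough pairs with the latest injection strictly
before it; the pair is usable when the gap is 5–28 h (inclusive).  When two
in-gap troughs share an anchor only the earlier one keeps it, so each
injection anchors at most one record.  All interval boundaries in the
pipeline (trough window, 20/30 h, 5–28 h, one-year lookbacks) are handled
with the conventions stated in the docstrings; the one-year lookbacks are
open intervals and lab lookups are strictly prior to the anchor to rule
out same-timestamp leakage.

**Target rules.**  Rule 1: an in-window trough makes the record its own
target.  Rule 2: otherwise the target is the daily dose of the earliest
subsequent record of the same patient whose trough is in the window; ties
on identical anchor times resolve to the larger daily dose (deterministic,
and conservative for under-dosed patients).  No admission boundary is
enforced on rule 2 — any later in-window record of the patient qualifies.
Targets that move the wrong way (larger than the current dose when the
trough was already above 20, smaller when below 14) are invalid.  Missing
and invalid labels are statuses, not errors; the cohort stage excludes
them (criterion 6).

**Acceptable range.**  `[min(0.85·t, t − 250), max(1.15·t, t + 250)]`
mg/day — the hull of a ±15 % band and a ±250 mg band; the absolute band is
wider below ≈1667 mg/day.  PAR membership is evaluated against this range
only, with inclusive bounds and no additional tolerance.

## Cohort

Exclusion criteria run in a fixed order (sub-10 mg doses, blank IDs,
missing weight, mistimed troughs, a pluggable timing predicate, bad
labels), so a record violating several is counted once, under the first.
Counts are reported in each criterion's natural unit (events, patients,
matches, records).  The criterion-5 predicate defaults to pass-through: it
exists as a hook because institutional definitions of "acceptable trough
timing" beyond the 5–28 h rule vary and no single rule is canonical.

Splitting is by patient (64/16/20 % train/validation/test by default).
Patients are ordered by a seeded `blake2b` hash of their ID and the order
is cut at the exact fractions: deterministic given the seed, independent
of record order, realized sizes within one patient of the targets.  This
trades away the full insertion-stability of a pure hash-threshold scheme
in exchange for exact fractions.

## Features

All features are computed strictly from information available before the
record's anchor time; the single deliberate exception is the daily
injection frequency, which counts administrations in the 24 h ending at
the anchor *including* the anchor administration itself (it is the
decision being featurized).  A time-shift property test pins this down.

* Renal function: Cockcroft–Gault creatinine clearance (mL/min) from age,
  weight, sex and the latest serum creatinine within one year; vancomycin
  clearance as `0.06 L/h per mL/min` with a 0.3 L/h anuric floor, fixed at
  0.48 L/h under hemodialysis (any session within the prior 7 days).  These
  are standard clinical estimates, chosen because the source features are
  named without formulas anywhere authoritative.
* Dispensing: counts per ATC level-1 letter over the prior year; never
  missing (zero when no rows).
* History features come in two variants: `*_no_filter` scans all raw
  events; `*_with_filter` scans only cohort-surviving records whose trough
  had already been measured by the anchor time.  With-filter history draws
  on the **full** labeled cohort (`history_records`), not the per-split
  subset — only the patient's own past is visible, so patient-disjoint
  splits stay leak-free while e.g. an initial record can feed its
  successor's history.
* Manifests: 15 features for the initial model, 17 for the subsequent one
  (the with-filter trough/dose pair, the no-filter trough and the
  trough-gap are meaningful only with prior lab history).  The matrix
  builder accepts any manifest; the defaults are curated, and
  `select_features` offers backward importance pruning for re-deriving a
  set on new data.

Missing values stay `NaN` end to end; LightGBM routes them natively and no
imputation ever occurs.

## Models and tuning

Both recommenders are LightGBM regressors with a squared-error objective
on the target daily dose, `num_leaves = min(2^depth, 128)`,
`min_child_samples = 5`, single-threaded deterministic training, and
suggestions floored at 250 mg/day.  Seven hyperparameters are searched:
`n_estimator` [50, 1000], `m_depth` [2, 12], `learning_rate`
[0.005, 0.3] (log), `reg_alpha`/`reg_lambda` [1e-8, 10] (log), and the two
column-sampling fractions [0.4, 1] (`colsample_bylevel` maps to LightGBM's
per-node feature fraction).  Stage 1 is a self-contained Tree-structured
Parzen Estimator: after 10 random start-up trials, trials are split at the
25 %-quantile of validation MAE, 24 candidates are drawn from a factorized
Gaussian KDE (bandwidth 0.15 in the unit-cube parametrization) over the
good set and ranked by the good/bad density ratio.  Stage 2 evaluates a
grid around the stage-1 optimum — by default three points each for
`n_estimator`, `learning_rate` and `m_depth` (27 fits) with the remaining
hyperparameters held at the optimum; a full seven-way grid is accepted via
config but disproportionate as a default.  Validation MAE is the selection
objective throughout (PAR is a step function and noisier to optimize);
`bayes_evals = 0` degrades gracefully to grid-only refinement.  The test
split is structurally unreachable from `tune`.

**PK baseline.**  A transparent one-compartment stand-in, not a
reproduction of any institutional nomogram.  Initial: invert the
steady-state trough equation (1 h infusion, 12 h interval, V = 0.7 L/kg,
CL from the clearance rule; 80 mL/min assumed when creatinine is missing)
at the window midpoint 17 mcg/mL; hemodialysis patients get 20 mg/kg per
48 h.  Subsequent: `last dose · 17 / observed trough`, clipped to
[250, 6000] mg/day, using the last *matched* dose–trough pair (the
previous surviving record's dose and the trough measured under it) —
pairing the newest raw dose with the newest raw trough would double-apply
any titration the physician already made in response to that trough.

**Attributions.**  LightGBM's built-in TreeSHAP
(`predict(..., pred_contrib=True)`): per-record attributions plus the base
value sum exactly to the raw prediction.

## Synthetic cohort

The generator draws demographics (age 63.1 ± 14.3 y, weight
64.7 ± 17.2 kg, 30 % female, 10 % hemodialysis), assigns true PK per
patient (one compartment; CL = 0.06·CrCl L/h with 0.3-lognormal
between-subject variability and a 0.3 L/h floor, ≈0.48 L/h under dialysis;
V = 0.7 L/kg with 0.1-lognormal spread), and simulates a 3–14 day course:
administrations every 8/12/24 h (48 h under dialysis), troughs drawn
shortly before a dose roughly every two days, measured values =
steady-state model trough × lognormal(0.15) residual.  The physician
policy starts at 15–20 mg/kg per 12 h equivalent and, on each measured
trough, titrates proportionally toward 17 mcg/mL with probability 0.8,
otherwise perturbs the dose randomly by ±30 % — deliberately imperfect so
that a substantial share of troughs misses the window and rule-2 labels
are exercised.  Chemistry labs exist within the lookback year for 61 % of
patients (stale beyond a year otherwise); ATC dispensing counts are
Poisson with modest means (the pipeline only consumes counts, so the
absolute dispensing intensity is kept small).  One seeded generator with a
child stream per patient makes tables reproducible and stable under
parameter changes.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: accumulation kinetics before steady state
(troughs are drawn from the steady-state equation from the first
measurement), loading doses, intra-patient renal-function drift, admission
structure, informative measurement timing, and correlated comorbidity
patterns.  Tests on this cohort demonstrate that the pipeline recovers the
structure it assumes; they say nothing about model performance on hospital
data.

A hidden truth table (true CL, V, interval, and the oracle daily dose whose
steady-state trough is exactly 17) is emitted for tests only.  The oracle's
PAR is well below 1 even with perfect knowledge, because measured troughs
carry residual noise and targets inherit the physician's 250 mg-rounded
titration grid — it is the ceiling against which the trained model is
judged.

Planted defects mirror the exclusion criteria: appended sub-10 mg and
blank-ID rows (strictly additive, planted after each patient's last event
so matching is undisturbed), blanked weights, troughs moved to 2 h after
their prior injection, and patients whose troughs are all forced
supra-therapeutic (no derivable label).  Ground-truth labels let tests
equate exclusion counts with planted counts, as deltas against the
defect-free run where the base cohort already has natural criterion-6
removals.

## Problem sizes and numerics

Default test problem sizes are 60–500 simulated patients for unit and
recovery tests and 2000 patients (≈5000 labeled records) for the
dosing-signal recovery check — large enough for the PAR orderings being
asserted to hold with wide margins.  Formula oracles run on ≥1000 random
instances each.  Determinism is asserted bitwise (same platform, single
thread).  Degenerate inputs are handled as statuses or typed errors, never
silently: empty aggregation windows, unmatched troughs, missing labs,
all-missing feature columns (warned, retained), empty metric inputs
(raise).

## Known limitations

* The exact feature lists of the reference models are not machine-readable
  anywhere; the defaults here are a faithful reconstruction (15/17
  features) and are configurable.
* The PK baseline is a generic one-compartment inversion; institutional
  nomograms differ in loading rules and rounding.
* Dose suggestions are continuous (no rounding to administrable 250 mg
  steps), matching how reference suggestions are printed.
* `aggregate_daily_dose` treats hemodialysis q48 h regimens like any
  other: the 20 h window then contains a single administration and the
  "daily dose" equals the per-dose amount, an artifact of the aggregation
  rule itself.
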