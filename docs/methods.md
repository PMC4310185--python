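# Methods

This note documents the models, conventions and numerical choices behind
`eventbank`, and what the synthetic experiments do and do not establish.

## Timeline and discretisation

Events are discretised onto a timeline of units 1..T.  The unit is
configurable (`day` or `month`); a month is defined as exactly 30 days
everywhere (date→index mapping, horizon and lookback conversion, kernel
bandwidths), so all arithmetic is deterministic and calendar-independent.
Kernel bandwidths and delays are specified in months and converted to
timeline units (×30 for day units); feature column names always carry
the month values, so column names are stable across discretisations.

Point entities increment the unit containing their start date.
Continuing entities increment every unit intersecting [start, end]; a
missing end date is treated as a single unit at the start (conservative:
no unbounded spans), and overlapping stays sum, so a unit's count can
exceed one.  Events starting after T are dropped with a logged warning
rather than raised, for ingest robustness.  Indices are 1-based.

## Kernels

The discrete uniform kernel uses half-open support: K(t) = 1/σ for
0 ≤ t < σ, zero otherwise.  The closed-interval continuous form would
carry discrete mass (σ+1)/σ; the half-open convention makes the kernel
sum to exactly 1 for every integer σ ≥ 1, so the feature equals the mean
event rate over its window.  The one-sided Gaussian
√(2/πσ²)·exp(−t²/2σ²) for t > 0 is evaluated pointwise at integer
offsets without renormalising the discrete sum (it matches the closed
form exactly; its continuous integral over (0,∞) is 1).  Its effective
support is truncated at 8σ past the delay, far below double-precision
relevance.

The feature at evaluation point t is X(t) = Σ_{h=0}^{t−1} K(h−d)·E(t−h).
The h = 0 term includes the assessment unit itself; readmission labels
therefore exclude same-unit admissions (below) to prevent label/feature
overlap.  A kernel with bandwidth σ and delay d sees event ages
[d, d+σ): the default six-kernel bank covers ages 0–36 months and
nothing older, which is what caps MR history at 36 months.

## Vocabulary

Per entity class, codes with fewer than `min_count` (default 50)
occurrences are pooled into a reserved rare pseudo-code, and at most
`max_size` (default 2,000) codes are retained, ranked by descending
count with lexicographic tie-breaks for determinism.  Counts are
computed on the derivation period only (events before the validation
point) to avoid using validation-era frequencies — the leak-safe reading
of "database-wide" counts.

## Cohort construction

Assessment points are placed at discharges of emergency-flagged
admissions (a config flag admits planned discharges too) occurring at or
after the discharge of the patient's first admission carrying a disease
code; a fixed-calendar-date mode is also provided.  The label at horizon
H months is 1 iff an emergency-flagged admission starts in the half-open
window (t, t + H_units] — strictly after the AP unit, because features
include the AP unit, and inclusive at the far end.

The temporal split assigns a patient to the derivation cohort iff they
have at least one AP strictly before the validation point, discarding
that patient's later APs; all remaining patients (first AP at or after
the validation point) form the validation cohort with all their APs.
Patient sets are disjoint by construction and derivation APs all precede
the validation point.

## Elixhauser baseline

The 30 comorbidity indicators are mapped from ICD-10 codes using the
Quan coding table bundled as CSV data (`eventbank/data/`).  Quan's table
distinguishes 31 categories; the two hypertension categories are merged
so exactly 30 indicators result.  Matching is prefix-based after
uppercasing and stripping dots; malformed codes are ignored with a
warning.  Hierarchy exclusions (complicated diabetes over uncomplicated,
metastatic cancer over solid tumour) are applied by default and can be
switched off.  Lookback windows (1 month and 36 months) are closed at
the AP end, so the index stay's own codes count.

## Feature assembly and transform

Feature sets follow a fixed recipe: `baseline_1M`/`baseline_3Y` =
demographics + 30 comorbidity flags over the named lookback; `MR` =
demographics + M×N temporal features; `MR_comorbidities` = MR + the
36-month flags.  Demographics are age in years at the AP (continuous by
default; binning is a config choice left to callers), a female
indicator, and postcode one-hot over categories seen in derivation rows,
with categories seen fewer than 50 times pooled (reusing the rarity
threshold) and unseen categories encoding as all zeros.

Every column is min-max normalised to [0,1] with parameters fitted on
derivation rows only, clipped (validation values can exceed the fitted
range), then square-root transformed; constant columns map to zero.
Matrices are assembled dense (a few thousand rows by ~10³ columns is
trivial) and converted to CSR before the solver when mostly zero — both
routes feed identical values to the model.

## Model and uncertainty

Per (feature set, horizon): logistic regression with elastic-net penalty
(l1_ratio 0.5), solver saga, regularisation strength chosen from
{0.01, 0.1, 1.0} by 5-fold cross-validated AUC on derivation rows with
seeded fold assignment; max_iter 200 at tol 1e−3 is a deliberate
compute/accuracy trade-off (AUC is rank-based and insensitive to the
last digits of the coefficients).  Tuning is per (set, horizon).  No
class reweighting.  An all-zero design short-circuits to the closed-form
intercept-only solution (saga's step size degenerates there).

AUC is computed as the normalised Mann–Whitney U from average ranks
(ties count ½).  The 95% CI uses the Hanley–McNeil variance
approximation by default, clipped to [0,1]; a DeLong
(structural-components) variance is available via
`auc_mann_whitney(..., ci_method="delong")`.

## Synthetic generator

The generator emulates the data regime the framework targets: ~2,000
patients over an 8-year span (month units, T = 96); admission episodes
(continuing, DRG-like codes, 1–2 ICD-10-like diagnosis codes each,
medications); standalone emergency-department visits; Zipf(1.1) code
frequencies over 230 diagnosis codes (the frequent head drawn from codes
that hit Elixhauser prefixes), 100 medication and 30 DRG codes, so a
sizeable below-50-count tail exercises rare-event pooling; diagnosis
codes roll up to one-letter block parents, exercising hierarchy
expansion.

The readmission model is a per-discharge Bernoulli with logistic link:
P(readmission within the 12-month ascertainment window after discharge d)
= expit(logit(p0) + Σ_k w_k·c_k(d)), p0 = 0.18, where c_k(d) counts
events of a designated entity in a designated lag window before d.
Default planted effects: weight 1.0 per recent emergency visit (age
< 3 months) and 1.0 per recent N18 (renal failure) diagnosis (age
< 3 months).  Two realism devices make these counts genuinely variable:
per-patient ED-visit rates are gamma-distributed (shape 0.5, mean 10
visits per span — a frequent-attender tail), and N18 is sticky (once
coded, recoded with probability 0.5 at later admissions), which also
gives the Elixhauser baseline a legitimate, weaker route to part of the
signal.

The hazard is realised by superposition so that the null model is
exactly memoryless: the baseline component p0 is supplied by a
homogeneous per-patient emergency-admission background with rate
−ln(1−p0)/W per unit (so an arrival lands in any W-unit window with
probability p0), and each discharge additionally spawns an emergency
readmission with the excess probability (expit(logit(p0)+lp) − p0)/(1−p0).
The marginal per-discharge probability equals the logistic hazard, but
with all weights zero no spawns occur and future admissions are
independent of history — a direct per-discharge draw of the full
probability would make the baseline itself self-exciting (pending
delayed readmissions let past admissions predict future ones), lifting
the null AUC well above chance.  Spawned readmissions arrive after a
geometric delay whose median drifts from 4 to 8 months across the study
span, emulating lengthening time-to-readmission and stressing the
temporal split (validation-era positives are systematically harder).

What the generator does **not** emulate: care-pathway structure between
codes, seasonality, coding drift, mortality/censoring, inter-hospital
transfers, or realistic marginals beyond order of magnitude.  Passing
recovery tests therefore shows that the pipeline extracts and models a
recent-history signal without leakage across the temporal split — not
that any particular AUC level would be attained on real cohorts.

## Recovery experiment sizes

The recovery study (`eventbank.experiments`) uses 2,000 patients per
seed over ten consecutive seeds, the 6-month horizon, MR versus
baseline_3Y, and a validation point after five of the eight study years
(mirroring a 5-year derivation / 3-year validation period split).  That
yields roughly 2,100 derivation and 550 validation APs and ~630 MR
columns per seed, and runs in a couple of minutes on one CPU.  The
null-generator check is evaluated on the mean AUC across the ten seeds:
a single-seed null AUC has standard error ≈ 0.05 at this validation
size, while the ten-seed mean is stable to ±0.02.

## Known limitations

* Month units with 30-day months drift against the civil calendar
  (~0.4%/year); irrelevant for synthetic data, a conscious trade for
  determinism on real extracts.
* Overlapping admission intervals sum, so continuing-entity counts may
  exceed one per unit; whether that is the intended semantics for real
  data is a modelling decision surfaced as documented behaviour.
* The elastic-net C grid is coarse; widen `ModelConfig.Cs` for final
  analyses.
* `attach_labels` scans each patient's emergency admissions per AP;
  fine at 10⁴ APs, not tuned for millions.
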