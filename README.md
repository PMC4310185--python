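# eventbank

Disease- and task-agnostic temporal feature extraction from hospital
administrative data, with an evaluation harness for unplanned-readmission
risk prediction.

## The problem

Hospital databases record a patient's history as timestamped *entities*:
admission episodes, emergency-department visits, coded diagnoses,
dispensed medications.  Risk models usually reduce this history to a
handful of hand-crafted indices (e.g. the Elixhauser comorbidity flags),
discarding most of the temporal information and requiring new feature
engineering for every disease and task.  `eventbank` instead treats the
history as a bank of event-count signals and extracts features
mechanically, the same way for every entity and every prediction task.

It is intended for biostatisticians and clinical data scientists who
need a reproducible, leakage-aware pipeline from raw event tables to a
model-ready feature matrix — and for method developers, who get a fully
synthetic EHR generator with a planted, recoverable risk signal to test
against.

## The method

1. **Entity schema → event series.**  Entity types form a tree (codes
   roll up to parent categories).  Point entities (diagnoses,
   medications, ED visits) and continuing entities (admission episodes)
   are discretised onto a timeline of units t = 1, …, T; each (patient,
   entity) pair yields a count series E_i(t), with continuing entities
   counting once in every unit they overlap.  Two heuristics control the
   number of series M: codes occurring fewer than 50 times are pooled
   into one rare pseudo-code per class, and at most the 2,000 most
   frequent codes per class are kept.

2. **One-sided multi-resolution filter bank.**  Each series is convolved
   with N causal kernels K_i with bandwidth σ_i and delay h_i:

       X_i(t) = Σ_{h=0}^{t−1} K_i(h − h_i) · E(t − h)

   The uniform kernel is K(t) = 1/σ for 0 ≤ t < σ (so a (σ, h) kernel
   reports the mean event rate over the window (t−h−σ, t−h]); a
   one-sided Gaussian K(t) = √(2/πσ²)·exp(−t²/2σ²) for t > 0 is also
   provided.  The default bank is uniform with (σ, h) =
   (1,0), (3,0), (6,0), (12,0), (12,12), (12,24) months: N = 6 kernels
   spanning 36 months of history, giving M × N temporal features per
   assessment point.

3. **Readmission evaluation protocol.**  Assessment points (APs) are
   placed at unplanned hospital discharges at or after a patient's first
   diagnosis of the disease under study; the label at horizon H is
   whether an emergency-flagged admission starts within (t, t+H].
   Derivation and validation cohorts are disjoint *both* in patients and
   in calendar time.  Four feature sets are compared — Elixhauser
   comorbidity baselines over 1-month and 3-year lookbacks, the
   auto-extracted temporal set (MR), and MR + comorbidities, each plus
   age/gender/postcode — using logistic regression with elastic-net
   regularisation on min-max-normalised, square-root-transformed
   features.  Discrimination is reported as the validation AUC
   (c-statistic, the normalised Mann–Whitney U) with Hanley–McNeil 95%
   confidence intervals.

## Worked example

No real hospital data are bundled (they are not public); the `simulate`
command generates a synthetic database with a planted dependence of
readmission risk on recent emergency visits and renal-failure diagnoses.

```yaml
# demo_config.yaml
min_count: 10
disease_codes: [E11]
horizons_months: [1, 6]
validation_date: 2008-01-01
feature_sets: [baseline_3Y, MR]
seed: 7
sim: {n_patients: 500, seed: 7}
```

```text
$ eventbank simulate --config demo_config.yaml --outdir demo
wrote 17080 events for 500 patients to demo
$ eventbank extract --config demo_config.yaml --outdir demo
M=133 series, N=6 kernels, M*N=798 temporal features; 509 derivation / 182 validation APs
$ eventbank evaluate --config demo_config.yaml --outdir demo
$ eventbank report --outdir demo
feature_set                      MR          baseline_3Y
horizon_months
1               0.472 (0.241,0.702)  0.552 (0.311,0.794)
6               0.667 (0.563,0.772)  0.543 (0.436,0.650)
```

Reading the output: 133 event series survived vocabulary pooling, each
convolved with the 6-kernel bank.  At the 6-month horizon the
auto-extracted features reach validation AUC 0.667 versus 0.543 for the
comorbidity baseline — the planted recent-history signal is visible to
the filter bank but largely invisible to comorbidity flags.  At the
1-month horizon this 500-patient demo has only 6 positive validation
labels, so both intervals are wide and the point estimates are
uninformative; the full-scale experiment below uses 2,000 patients per
seed.

Artifacts written per run: `events.csv`, `demographics.csv`,
`schema.csv`, `truth.yaml` (planted-effect → feature-column map),
`ap_table.csv`, `vocabulary.csv`, `features_<set>.csv`,
`transform_params_<set>.csv`, `results.csv`, `coefficients_*.csv`, and a
`manifest.json` with the config digest and seed.

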