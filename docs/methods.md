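# Methods

## Data model

A cohort is a demographics table (one row per patient: birth year, sex,
race, ethnicity, state, inpatient and emergency-department visit counts)
plus an event table (one row per coded clinical event) and an inclusive
study window, defaulting to 2017-01-01 … 2019-12-31. Events carry exactly
one of three data types with a fixed terminology: diagnoses (ICD-10),
medications (RxNorm ingredient concepts), laboratory results (LOINC, with a
numeric value and a unit string). Diagnosis events additionally carry a
care setting (inpatient / outpatient / ed); whether a given source system
records setting reliably varies in practice, so it is modelled as ordinary
event data and only used where a definition asks for it.

Code matching normalises codes by upper-casing and stripping dots, then
tests exact membership or prefix containment. ICD-10 sets use prefix mode
because definitions cite family codes (E11) while records carry child codes
(E11.9, E11.65). The "other" sex/race/ethnicity categories represent
missing entries and are carried through untouched, never imputed.

## Synthetic cohort generator

The generator does not simulate disease biology. The downstream analysis
depends only on *which data-type combinations can identify a patient*, so
each patient draws a latent evidence class: one of the 7 non-empty subsets
of {DX, RX, LAB}, or "none". Class defaults give every subset probability
≥ 0.05 and "none" 0.22, so ~78 % of patients carry some qualifying
evidence. A class member type receives patterns satisfying the strictest
shipped criterion for that type — two T2D diagnoses on distinct days (and
within a 730-day span, inside the trailing two years of the window), two
elevated HbA1c results (LOINC 55454-3, values ~N(8.3, 1.4)% clipped to
≥ 6.6) on distinct days, at least two antidiabetic dispensings — which
makes stratum-level assertions exact rather than probabilistic.

Background (non-qualifying) events are layered on for everyone at 5
diagnosis, 3 medication and 4 laboratory events per patient-year, spread
uniformly over the window. These rates are a design choice (they are not
identifiable from published summaries); they are set high enough that
perturbation curves are non-degenerate. Background laboratory values stay
below diagnostic thresholds — HbA1c ~N(5.55, 0.35)% clipped to [4.8, 6.4],
so the pre-diabetic 5.6–5.8 % band is populated; random glucose is clipped
below 200 mg/dL, fasting below 126 — and background diagnosis/medication
codes avoid both the T2D code sets and the Charlson categories.

Demographics: age at study start uses a truncated normal on [18, 90].
Because truncating N(62.4, 15.4²) to that range shifts the realised mean to
≈ 61.2 years, the underlying normal parameters are moment-matched
numerically so the *truncated* distribution has mean 62.4 and SD 15.4.
Categorical fields are independent draws from the calibrated proportions;
visit counts are Poisson with the stated means (0.657 inpatient, 1.01 ED).
Poisson under-disperses relative to the observed SDs (1.61, 3.61) — visit
counts feed no phenotype logic, so matching the mean suffices here.

Comorbidities: each of the 17 Charlson categories is an independent
Bernoulli per patient with base prevalences chosen to be plausible for an
older, diabetes-enriched urban cohort, times a single global multiplier.
Since the expected mean index under independence is Σ min(m·p_c, 1)·w_c in
closed form, the multiplier is solved by bisection so the expected mean
equals the 2.17 target; sampling error at n = 100,000 is ≈ 0.007. The two
diabetes categories use type-1 (E10.x) representative codes so comorbidity
events never intersect the T2D qualifying set or the inaccuracy replacement
pool. Note that full-cohort Charlson means computed over *all* diagnosis
events run ≈ 2.6, because T2D-qualifying E11 events legitimately score the
diabetes category on top of the calibrated comorbidity stream; the 2.17
calibration is defined over the comorbidity stream alone.

Everything is a pure function of (profile, seed): byte-identical cohorts
under identical inputs.

## Phenotype language and evaluator

A criterion = (data type, code set, min_count, distinct_days?, setting?,
window_days?, value predicate?). Semantics: at least `min_count` matching
events inside the evaluation window, counted on distinct calendar days when
flagged, all falling within some `window_days`-day span when set. Value
predicates compare laboratory values against a threshold *and require the
unit string to equal the expected unit exactly* — no auto-conversion. That
strictness is deliberate: it is precisely the failure mode the
unit-corruption operator must expose.

Pathways are conjunctions of criteria; a definition is a disjunction of
pathways, evaluated on events restricted to its reference period (the
trailing `reference_period_days` of the study window; CCW's 730 days span
2018-01-01 … 2019-12-31 under the default window). A patient's data-type
stratum is the union of data types over *satisfied* pathways — not the data
types merely present in the record. This is the only reading under which a
definition without any medication+laboratory pathway shows a structurally
zero RX+LAB stratum while its LAB-only stratum is populated.

The five shipped definitions are best-effort encodings of the published
algorithms within this language, and are configs, not code: the engine
enforces only each definition's structural signature (CCW diagnosis-only
with 730-day period; JHU exactly three single-type pathways; eMERGE without
DX-only/RX-only/RX+LAB-only pathways; SUPREME-DM without RX-only pathways).
Exact thresholds (HbA1c ≥ 6.5 %, random glucose ≥ 200 mg/dL, fasting
≥ 126 mg/dL) follow the source definitions' laboratory criteria.

The vectorised evaluator is checked in the test suite against an
independent brute-force reference (per-patient linear scans, exhaustive
span enumeration) on randomised small cohorts, for all five definitions.

## Perturbation operators

Per-event randomness comes from a counter-based scheme: splitmix64-style
hashing of (seed, event id, role) yields stable uniforms, so the selected
set at fraction f₁ is a subset of that at f₂ ≥ f₁ under one seed. Identified
counts are therefore *exactly* non-increasing along a drop grid per seed,
which the suite asserts over the full default grid.

* **drop** — remove targeted events with drop-uniform < f; grid 0 … 1 by 0.1.
* **replace_code** — selected events get a different code drawn uniformly
  from a per-type pool excluding the current code (an event never keeps its
  code); the default pool is the observed vocabulary of that data type,
  i.e. T2D and non-T2D codes alike. Event counts are conserved.
* **scale_lab_value** — every laboratory value v → v·(1+δ), deterministic;
  grid −1.00 … +0.10 by 0.02 (56 points). The multiplicative reading is the
  only one that is coherent across analytes with different scales.
* **corrupt_units** — US→UK reporting: glucose mg/dL → mmol/L (÷ 18.016,
  the molar mass of glucose), HbA1c NGSP % → IFCC mmol/mol via the master
  equation 10.93·x − 23.50. Values are transformed and units relabelled;
  unmatched (code, unit) pairs pass through.
* **shift_dates** — forward by exactly d calendar days, d on the 30-day
  grid plus 365. Attrition arises because the fixed study window then
  excludes late events; no resampling.
* **compound** — children applied in order; the patients table is never
  touched by any operator.

## Experiment grids

`run_grid` sweeps one axis × targets × levels × replicate seeds, re-applies
every definition, and reports the identified count plus two retentions:
against the same seed's level-0 baseline (the primary curve) and against
the whole cohort denominator (the alternative normalisation, since either
reading of "percent identified" is defensible). Stochastic axes default to
5 replicate seeds; value scaling and date shifting are deterministic and
run once. The compound inaccuracy axis replaces diagnosis and medication
codes and leaves laboratory events alone (their values are manipulated on
their own axis).

The overlap partition counts patients identified by *exactly* each of the
31 non-empty subsets of the five definitions; regions are disjoint and sum
to the union. Charlson scoring sums category weights with each category
counted once; the Quan ICD-10 prefix map with original weights (1/2/3/6) is
shipped as a replaceable YAML data file with pairwise-disjoint prefixes.

## Problem sizes

The bundled analysis runs at 20,000 patients (~830k events), where every
stratum and overlap region populates comfortably; calibration statistics
are computed at 200,000 patients (demographics) and 100,000 (Charlson).
Tests use 400–20,000-patient cohorts depending on what they assert.

## What passing tests do and do not show

The generator reproduces published *marginal* summaries and the structural
evidence-class layout; it does not reproduce real-data correlations (age ×
comorbidity burden, utilisation × disease severity), coding practice
drift, or a realistically long-tailed code vocabulary. Two consequences to
keep in mind:

* Identified-count levels are properties of the synthetic evidence-class
  mix, not estimates of any health system's true counts. Only structural
  results (which strata are zero, which definitions vanish under which
  defect) transfer as-is.
* With the observed-vocabulary replacement pool (~30 distinct diagnosis
  codes at desk scale), code replacement is bidirectional: single-code
  definitions can *gain* patients because a background event has a
  non-trivial chance of being replaced into an E11 code. Against a real
  vocabulary of tens of thousands of codes that chance is negligible and
  all definitions decline. The pool is a parameter; pass a curated or
  enlarged pool to study that regime.

Other known limitations: missingness is uniform-at-random by design (no
MAR/MNAR structure); date shifts are uniformly forward; comorbidity
categories are independent (no co-occurrence structure); the reported
non-integer median Charlson score of the source population (1.33) implies
an averaging scheme over periods that is not modelled — the generator
targets the mean only.
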