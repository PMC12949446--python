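# Methods

This note documents the models, conventions and defaults behind
`sepsisval`: what each stage computes, which choices were genuinely open,
and what the synthetic cohorts do and do not establish about real data.

## Outcome phenotyping

### SOFA scoring

The six organ-system subscores (respiration, coagulation, liver,
cardiovascular, CNS, renal; 0–4 each) follow the standard consensus
cut-point table, encoded as a versioned lookup (`SOFA_TABLE_VERSION`) so a
site using a local dialect can swap it. Inputs are unit-normalised:
PaO2/FiO2 ratio (unitless), platelets ×10³/µL, bilirubin mg/dL, MAP mm Hg,
vasopressor rates µg/kg/min, GCS 3–15, creatinine mg/dL. Values outside
plausible physiologic ranges are clamped with a logged warning rather than
rejected — dirty EHR feeds are data, not errors.

Time-resolved evaluation carries each input forward for a per-kind
lookback: labs 24 h, vitals 8 h, GCS 24 h, vasopressor rates 4 h (all
configurable). These are common electronic-SOFA conventions; no single
published convention exists, which is why they are config-exposed rather
than fixed. Vasopressor exposure is represented as infusion-rate
observations with a short lookback — one carry-forward mechanism for all
inputs — rather than as explicit administration intervals; with 15-minute
rate charting the two are equivalent, and the lookback is the conservative
choice when charting is sparser. A missing input scores 0 and is flagged in
`missing_components`: assuming absent evidence of dysfunction is standard
practice and conservative for onset detection. The respiration rows 3–4
require respiratory support; without a support flag the component caps
at 2. Urine-output renal criteria exist behind a flag but default off —
reliable urine totals are rarely available at scoring resolution.

The score is right-continuous and piecewise constant between observations,
so the ≥ 2-point "delta crossing" scan evaluates only at observation
timestamps. Baseline conventions: `zero` (default — no prior dysfunction
assumed), `first_observed` (the total at the first evaluation time, which
absorbs chronic dysfunction), and `pre_window_min` (the running minimum of
the total up to each time, i.e. the best state seen so far). The default
matters: with `zero`, a chronically dysfunctional patient can cross at
their first observation.

### Sepsis-3 labeling

Suspected infection (SI) requires a body-fluid culture order and a
qualifying antibiotic course: doses are chained into courses when
consecutive doses are ≤ `max_dose_gap_hours` apart (default 96 h — the
two-dose rule has no published spacing; 4 days bounds a plausible single
treatment course), a course qualifies with ≥ 2 doses, and the pair
qualifies when the first dose lies in [culture − 72 h, culture + 24 h],
edges inclusive. SI time is min(culture time, first dose time), the
standard operationalisation. An encounter is septic when a SOFA delta
crossing starts within [SI − 48 h, SI + 24 h], edges inclusive.

The onset anchor is configurable. The default, `later_of_pair`, reads
"the first time the criteria are met" literally: over all qualifying
(SI, crossing) pairs, the minimum of max(SI time, earliest in-window
crossing). `si_time` and `sofa_time` anchors support sensitivity analyses.
A subtlety worth noting: enlarging the four SI/dysfunction windows can only
add qualifying pairs (monotone), but enlarging the course gap is *not*
monotone — merging courses moves first-dose times and can disqualify a
pair; the property tests respect that distinction.

Clinician recognition is the earliest antibiotic order (falling back to the
first administration when no order event exists), lactate order, or
body-culture order strictly before onset, defaulting to onset itself when
none precedes it. Simultaneous indicators are broken by the fixed
precedence antibiotic < lactate < culture, purely for determinism.

## Cohort filters

Reasons are applied in fixed order, first match wins, and the ledger always
conserves counts (included + excluded = input): under-age (< 18 y); no
prediction from a required model; outcome (onset, death, or discharge)
before the first score — anchored at the latest of the required models'
first prediction times; first-hour no-CBC exclusion.

The first-hour rule mirrors how CBC-dependent scores behave at deployment:
an encounter with a CBC result inside the first hour is never censored;
otherwise the CBC-dependent model's scores before hour 1 are dropped, and a
septic encounter whose onset falls inside that first hour with no CBC at or
before onset is excluded from **all** models' analyses for consistency. The
"first hour of evaluation" is anchored at presentation (ED arrival or
direct admission). Post-onset truncation keeps predictions with
`ts < onset` strictly — a score at the onset instant cannot inform an early
warning. Encounters left with zero retained predictions for a required
model after censoring (rare, very short stays) are excluded under `other`.

## Evaluation

* **AUROC** is the Mann–Whitney probability with ties counted ½, computed
  by ranks; it matches pair-counting enumeration exactly and is invariant
  to monotone score transforms.
* **Threshold calibration**: the largest integer threshold whose
  encounter-level sensitivity (with the ≥ convention — "exceed" read as
  meets-or-exceeds, matching integer score granularity) still meets the
  target (default 0.60). Largest ⇒ maximal specificity subject to the
  sensitivity floor; threshold 0 is always feasible.
* **Encounter level**: classification by max retained score; the alert
  time is the first threshold crossing; lead time = onset − first crossing
  over true positives, summarised as median (IQR).
* **Prediction level**: each retained prediction (t, s) is positive iff
  onset T exists with t < T ≤ t + H (hospitalization horizon: any T > t);
  metrics are pooled across encounters, at the same threshold as the
  encounter-level analysis. Positive counts are non-decreasing in the
  horizon by construction. NNE = round(1/PPV) from the unrounded PPV.
  Per-encounter averaging instead of pooling is deliberately not offered
  as a default — pooling is what deployed-score reports use.
* **Bootstrap**: percentile intervals, resampling encounters with
  replacement (all of an encounter's predictions travel with it),
  preserving within-encounter correlation; degenerate resamples (a single
  class) are skipped and counted, and more than 50% degenerate is an
  error. For speed, the production path aggregates per-encounter score
  histograms (101 integer bins) and computes weighted confusion cells and
  a tie-aware weighted AUROC per resample — algebraically identical to
  recomputing from raw predictions.
* **Calibration curves**: predicted risk = score/100, equal-count bins
  (default 10), bins merged when distinct scores run out.
* **Re-anchoring**: the comparison event moves from onset to the
  recognition indicator (composite or single-indicator variants); the
  truncation and all downstream metrics are recomputed against the new
  anchor. When scores ramp toward onset and recognition precedes onset,
  re-anchoring removes the most informative scores, so discrimination can
  only be expected to drop — the direction the harness's tests check.

## Fairness and alert burden

The audit stratifies by age band (18–44, 45–64, 65–79, ≥ 80 — configurable;
no canonical banding exists), sex, race (Asian, Black, White, other,
unknown; unrecognised values map to unknown with a logged warning) and
ethnicity, reporting n, sepsis incidence, median (IQR) of the encounter max
score, and subgroup AUROC with a bootstrap CI — flagged undefined below two
encounters in either class.

Every retained prediction at or above the alert threshold is an alert.
Silencing is a greedy per-encounter scan keeping an alert iff ≥ 8 h (the
default window) after the last kept alert; a continuous alerter of duration
D therefore keeps exactly ⌈D/8 h⌉ alerts. Burden curves re-index alerts to
time since presentation and divide by the encounters still in hospital at
each bin start, so late bins are not diluted by discharged patients.
Silencing is per encounter, not per unit or clinician — it models the
hypothetical workflow, not a paging system.

## Synthetic cohorts

The generator emulates the statistical structure of multicenter inpatient
validation cohorts. Defaults (all configurable, chosen once as realistic
study conditions):

| Parameter | Default | Emulates |
|---|---|---|
| sepsis incidence | 0.05 | encounter-level rates of a few percent (2–7%) |
| time to onset | log-normal, median 5 h, log-SD 1.6 | medians of 4–10 h with a heavy right tail |
| LOS, septic | log-normal, median 7 d, log-SD 0.8 (≥ onset + 12 h) | week-long septic stays |
| LOS, non-septic | log-normal, median 0.8 d, log-SD 1.2 | mostly brief ED/observation stays |
| score cadence | 15 min | deployed scoring frequency |
| first-hour CBC probability | 0.5 (else first CBC in hour 1–2) | first-hour no-CBC exclusion of ~10–30% among septic |
| target AUROC (v2-like / v1-like) | 0.85 / 0.72 | a revised model and its weaker predecessor |
| recognition indicator probability | 0.6, lactate order 0.5–4 h pre-onset | clinician workup preceding positivity |

Septic encounters carry streams constructed to satisfy the labeler exactly
at the ground-truth onset: a culture order at the SI anchor, a two-dose
antibiotic course starting 30 min later, and a creatinine jump to
3.0 mg/dL (renal 2) up to 6 h before. Non-septic encounters include
deliberate near-misses — cultures with qualifying antibiotic courses but no
dysfunction, and one-point dysfunction without infection workup — so the
labeler's specificity is genuinely exercised. A `borderline_fraction`
places crossings exactly on the +24 h window edge and flags them in the
truth table (default 0).

### Surrogate score process

The latent risk on the grid is
`L(t) = base + τ·g + ramp(t) + jitter·e(t)` with `g ~ N(0,1)` per
encounter (shared between the two models of one encounter), i.i.d.
per-prediction jitter, and a linear ramp rising to `ramp_height` over the
final `ramp_window_h` (8 h) before onset; scores are
`round(100·expit(L))`. Defaults: base −2.2, ramp height 3.0, jitter
SD 0.3.

The encounter-level statistic is the **maximum** score over a
variable-length series, so no closed form links τ to the encounter-level
AUROC (the binormal formula does not survive the max). For a requested
target, τ is found by bisection against a Monte-Carlo simulation of the
max statistic (25 000 encounters per class, common random numbers across
bisection steps, a fixed internal calibration seed). Consequences worth
knowing: the process for a given target is *one fixed process* independent
of the cohort seed (which is what makes "the generator truth" well-defined
for coverage studies), calibration is cached per parameter set, and
empirical cohort AUROCs recover the target to well within ±0.02 at
n = 10 000. The "v1-like" surrogate is the same process with a larger τ.

Numerical conventions: grid times are `i·cadence` with `t < min(onset,
discharge)`; onsets are clipped to [0.3 h, 14 d] and non-septic stays to
[0.5 h, 60 d] (negligible mass moved; keeps series lengths bounded);
timestamps are rounded to whole seconds everywhere so that labeling
recovers ground-truth onsets exactly and serialisation round-trips
bit-for-bit.

### What the synthetic cohorts do not show

The generator reproduces timing structure, censoring mechanics and
tunable discrimination — not physiology. Labs are placed to satisfy or
violate the phenotype by construction, so the ≥ 99% generator–labeler
agreement validates window logic, not chart-review concordance of Sepsis-3
abstraction on real charts. Demographics are sampled independently of the
score process by default, so the fairness audit's null behaviour is
exercised (differential incidence is available via
`incidence_multipliers`); nothing is claimed about real subgroup equity.
Score dynamics are a ramp plus noise, not model-specific failure modes
(e.g. missingness-driven artifacts). Passing tests establish the harness's
correctness; they are not external evidence about any deployed model.

## Problem sizes used by the shipped checks

The test suite and acceptance script scale simulations to what the
properties need: labeler agreement at n = 5000; parameter recovery at
n = 10 000 per target with incidence 0.20 (higher-than-default incidence
shrinks the Monte-Carlo error of the empirical AUROC without touching the
recovery band; the CBC rule is off there because the quantity under test is
the score process, not the censoring); bootstrap coverage over 200 worlds
of n = 2000 at incidence 0.25 with B = 500; re-anchoring direction over 30
cohorts of n = 1500 at incidence 0.10; the acceptance script runs the full
pipeline once at n = 20 000 under the default conditions with B = 200
(its JSON reports point estimates).
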