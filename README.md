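# sepsisval

A validation harness for inpatient sepsis early-warning scores.

Hospitals increasingly deploy proprietary models that emit a 0–100 sepsis
risk score for every ED and inpatient encounter on a 15-minute cadence.
Evaluating such a model against the Sepsis-3 outcome definition requires a
surprising amount of machinery — electronic phenotyping of raw EHR event
streams, careful censoring rules, time-anchored metrics — and each piece has
edge cases that silently bias the result. `sepsisval` packages that
machinery as a tested, reusable pipeline for biostatisticians and clinical
informaticists running local validations:

* **Sepsis-3 electronic phenotyping.** Suspected infection = a body-fluid
  culture order co-occurring with the first dose of at least 2 antibiotic
  doses administered between 72 h before and 24 h after the culture order.
  Organ dysfunction = a rise of ≥ 2 points in the Sequential Organ Failure
  Assessment (SOFA) score above encounter baseline, between 48 h before and
  24 h after suspected infection. Onset (time of sepsis positivity) is the
  first instant both criteria have occurred. All windows, the dose rule and
  the onset anchor are configurable.
* **Time-resolved SOFA scoring** (six systems, 0–4 each) from long-format
  observation streams, with per-kind carry-forward lookbacks and selectable
  baseline conventions.
* **Cohort censoring**: adults only, encounters whose outcome precedes the
  first score, first-hour left-censoring of CBC-dependent scores, and
  strict pre-onset truncation — all tracked in an exclusion ledger.
* **Evaluation**: encounter-level (max score, first threshold crossing,
  lead time) and prediction-level (4 h / 12 h / hospitalization horizons)
  AUROC, sensitivity/specificity/PPV/NPV, NNE = round(1/PPV), thresholds
  calibrated to a target sensitivity (default 60%), percentile bootstrap
  CIs resampling *encounters*, calibration curves, and re-anchoring of the
  comparison event to clinician recognition (earliest antibiotic, lactate
  or culture order before onset).
* **Reporting**: subgroup fairness audit (age, sex, race, ethnicity) and an
  alert-burden simulation with an 8-hour silencing policy.
* **Synthetic EHR cohorts**: a generator that emulates the statistical
  structure of multicenter inpatient cohorts (incidence of a few percent,
  heavy-tailed onset times, short non-septic stays) and produces surrogate
  score series whose encounter-level AUROC is *calibrated by construction*
  to a requested target — so every stage of the pipeline is testable
  end-to-end without access to protected health data.

## Worked example

```python
import sepsisval as sv

config = sv.PipelineConfig(
    sim=sv.SimConfig(n_encounters=2000, sepsis_incidence=0.05, seed=7),
    evaluation=sv.EvalConfig(n_bootstrap=200, prediction_level_ci=False),
    fairness_bootstrap=50,
)
bundle = sv.run_pipeline(config)

enc = bundle.metrics.query("level == 'encounter' and anchor == 'sepsis_onset'")
for model in ("esm_v2_like", "esm_v1_like"):
    row = enc[(enc.model_id == model) & (enc.metric == "auroc")].iloc[0]
    print(f"{model}: threshold {bundle.thresholds[model]}, "
          f"AUROC {row.estimate:.3f} (95% CI {row.ci_low:.3f}-{row.ci_high:.3f})")
```

prints

```
esm_v2_like: threshold 56, AUROC 0.829 (95% CI 0.782-0.867)
esm_v1_like: threshold 37, AUROC 0.676 (95% CI 0.604-0.733)
```

The stronger surrogate ("v2-like", target AUROC 0.85) is scored at the
largest integer threshold keeping encounter-level sensitivity ≥ 60% (56
here), and its bootstrap interval comfortably excludes the weaker "v1-like"
surrogate (target 0.72) — the qualitative ordering a validation of a
revised model against its predecessor looks for. Continuing with the same
bundle:

```
sens 0.61  spec 0.86  PPV 0.15  NPV 0.98  lead time 2.5 h
NNE by horizon: {'4h': 56, '12h': 43, 'hospitalization': 40}
ledger: {'under_age': 0, 'no_prediction': 0, 'outcome_before_first_score': 0,
         'first_hour_no_cbc_septic': 7, 'other': 0, 'included': 1993}
alerts raw -> silenced: 78429 -> 3472
```

PPV of 0.15 at 60% sensitivity means roughly one true sepsis case per seven
encounter-level alerts; the NNE row says a team reviewing every
above-threshold *prediction* would evaluate ~56 alerts per case arising
within 4 hours. Seven septic encounters were excluded because they became
septic inside the first hour with no CBC result yet (the left-censoring
rule), and 8-hour silencing cuts raw alert volume by ~95% without changing
accuracy.

The same run is available from a shell:

```bash
sepsisval all --config run.yaml --out report/ --seed 7
```

where `run.yaml` holds the config sections (`sim:`, `evaluation:`, ...);
`sepsisval simulate/label/evaluate/report` expose the individual stages.
The report directory contains `metrics.csv`, `labels.csv`,
`exclusions.csv`, `fairness.csv`, `alert_burden.csv`,
`calibration_<model>.csv`, `thresholds.json` and a `manifest.json` that
suffices to re-run the pipeline bit-identically.

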