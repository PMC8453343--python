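# telemon

Adherence and blood-pressure analytics for daily home-telemonitoring
programs for hypertension, plus a synthetic cohort generator so the whole
pipeline runs and is testable without any patient data.

## The problem

Home blood-pressure telemonitoring only works if patients actually transmit
readings every day. Programs for Medicaid populations typically ask each
patient to measure SBP, DBP and pulse daily by a self-selected deadline; a
staff member places an *adherence reminder call* when the deadline is
missed, and a clinical alert fires when a transmitted reading falls outside
the patient's physician-assigned *alert range*. This package implements the
analysis such a program needs, for biostatisticians and program evaluators:

* **Transmission events.** Each patient-day is classified as NT (no
  transmission), ORT (out-of-range transmission) or IRT (in-range
  transmission); bounds are inclusive, default ranges 90–160 / 60–90 mm Hg
  and 60–120 bpm.
* **Adherence metrics.** Pre- vs post-call transmission rates (the
  difference is the call-attributable gain), monthly and weekday
  breakdowns, missed-call rates, percent-in-range
  100·#IRT/(#IRT+#ORT), and adherent/nonadherent cohorting (transmitting
  on ≥ 80% of the 150 analysis days, i.e. ≥ 120 days, after a 30-day
  washout).
* **Next-day transition analysis.** The pooled first-order transition
  matrix P(next event | today's event), the conditional adherence
  100 − P(NT|s) and conditional in-range share
  100·P(IRT|s)/(P(ORT|s)+P(IRT|s)) it implies, empirical (window-censored)
  gaps to the next in-range transmission, and analytic expected hitting
  times of the three-state Markov chain.
* **Blood-pressure outcomes.** Month-1 vs month-5 change per cohort
  (positive = improvement) with paired and between-cohort t tests, and the
  uncontrolled subgroup (month-1 means strictly above 140/90).
* **Unmet need.** The estimated count of missed days whose readings would
  have been out of range, (1 − post rate) × out-of-range fraction × days —
  lost opportunities for clinical follow-up.
* **Synthetic cohorts.** A seeded generator whose defaults reproduce the
  study conditions of a 2093-patient enrollment funnel (823 eligible: 475
  adherent / 348 nonadherent) with published transition matrices, call
  behavior and blood-pressure distributions; see `docs/methods.md`.

## Worked example

```python
from telemon import (default_config, generate_cohort, filter_eligible,
                     apply_washout, classify_events)
from telemon.adherence_metrics import (classify_cohorts, transmission_rate,
                                       percent_in_range)
from telemon.transition_analysis import (estimate_transition_matrix,
                                         event_sequences, conditional_adherence)
from telemon.unmet_need import estimate_unmet_need

cfg = default_config(seed=1)
patients, records = generate_cohort(cfg)
records, n_excluded = filter_eligible(records, min_days=180)
records = apply_washout(records, washout_days=30, analysis_days=150)
records = classify_events(records, patients)
cohorts = classify_cohorts(records, threshold=0.8)

adherent = cohorts.index[cohorts == "adherent"]
print(f"{len(patients)} enrolled, {records.n_patients} eligible, {len(adherent)} adherent")
print(f"adherent pre-call rate:  {transmission_rate(records, 'pre', patient_ids=adherent):.1f}%")
print(f"adherent post-call rate: {transmission_rate(records, 'post', patient_ids=adherent):.1f}%")
print(f"adherent in-range share: {percent_in_range(records, patient_ids=adherent):.1f}%")

m = estimate_transition_matrix(event_sequences(records), patient_ids=adherent)
print(f"P(IRT | NT) next day:    {m.probs.loc['NT', 'IRT']:.1f}%")
print(f"adherence after a miss:  {conditional_adherence(m, 'NT'):.1f}%")

est = estimate_unmet_need(records, cohorts)
print(f"unmet need: {est.total_days} missed out-of-range days "
      f"({est.overall_pct:.1f}% of patient-days)")
```

prints

```
2093 enrolled, 823 eligible, 475 adherent
adherent pre-call rate:  75.4%
adherent post-call rate: 91.8%
adherent in-range share: 61.6%
P(IRT | NT) next day:    37.8%
adherence after a miss:  67.6%
unmet need: 12533 missed out-of-range days (10.2% of patient-days)
```

The pre-call rate is what patients transmit unprompted; the ~16-point gap
to the post-call rate is what the reminder calls add. The day after a
missed transmission, adherence (67.6%) is far below the cohort average —
missed days cluster. The unmet-need line estimates how many of the missed
days would have carried an out-of-range reading nobody saw.

### Command line

```sh
telemon simulate --seed 17 --out sim/            # patients.csv + daily.csv + config.yaml
telemon analyze adherence --daily sim/daily.csv --patients sim/patients.csv --out results/
telemon report --simulate --seed 17 --out report/   # full bundle + report.md
```

`telemon report` writes every stage's CSVs, a Markdown report with the
monthly, weekday, transition, blood-pressure and unmet-need tables, and a
`run_metadata.json` sidecar (config hash, seed, stage-by-stage patient
accounting). Identical config and seed give a byte-identical bundle.

## Layout

```
src/telemon/
  io_model.py             domain types, CSV I/O, eligibility, washout, classification
  synthetic_data.py       simulation config + seeded cohort generator
  adherence_metrics.py    transmission rates, weekday tables, cohorting
  transition_analysis.py  transition matrices, conditionals, gaps, hitting times
  bp_outcomes.py          month-1 vs month-5 blood-pressure changes
  unmet_need.py           missed out-of-range day estimation
  stats_util.py           test-statistic and rounding conventions
  report.py, cli.py       pipeline orchestration and the telemon CLI
```

`docs/methods.md` documents the model assumptions, generator design, and
numerical conventions in detail.
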