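# Methods

## The analysis problem

`telemon` analyzes daily home-telemonitoring programs for hypertension in
which each enrolled patient is asked to measure and transmit systolic blood
pressure (SBP), diastolic blood pressure (DBP) and pulse every day by a
self-selected deadline, and a staff member places an adherence reminder call
whenever the deadline is missed. The unit of analysis is the *patient-day*,
and each monitored day ends in exactly one of three transmission events:

* **NT** — no transmission by end of day;
* **ORT** — a transmission with at least one vital strictly outside the
  patient's physician-assigned alert range;
* **IRT** — a transmission with all vitals inside the range.

Range bounds are inclusive: a reading equal to a bound is in range. "Out of
range" is strict exceedance. A day's event is judged on the *post-call*
transmission status; the pre-deadline flag feeds only the pre/post rate
decomposition that quantifies what the reminder call adds.

The pipeline stages are: eligibility filtering (≥ 180 consecutive monitored
days), a 30-day washout (equipment learning period), trimming to a 150-day
analysis window renumbered 1..150, per-day event classification, adherence
metrics, next-day transition analysis, month-1 vs month-5 blood-pressure
change analysis, and unmet-need estimation.

## Conventions fixed by the package

* **Months are 30-day blocks** of renumbered study days (month *m* = days
  30(m−1)+1 .. 30m), not calendar months: a 150-day window then has five
  equal months. Weekday, in contrast, is taken from the calendar date, so
  each 30-day month contains 4–5 of each weekday.
* **Rates are micro-averages**: one numerator and one denominator pooled
  over the patient-days in scope (100 × transmitting patient-days /
  patient-days), not means of per-patient rates.
* **Cohorting**: a patient is *adherent* when post-call transmissions cover
  at least ceil(threshold × analysis days) days — inclusive at the
  boundary, so 120 of 150 qualifies at the default 80% threshold. The
  threshold-days computation subtracts 1e-9 before the ceiling because
  0.8 × 150 is 120.000…01 in binary floating point.
* **SD conventions**: weekday-table summary rows use the population (÷n)
  convention; blood-pressure tables use the sample (÷(n−1)) convention,
  consistent with the t statistics computed from them.
* **Rounding**: percentages and mm Hg values are printed to one decimal
  with ties going away from zero; rounding happens only at render time
  (the Markdown report), never inside computations. The one deliberate
  exception is the unmet-need total, whose published reporting convention
  rounds per-patient values to two decimals before multiplying by cohort
  sizes; the reporting path reproduces that exactly while the internal
  path keeps full precision.
* **Statistical tests** are all two-tailed: pooled two-proportion z,
  Pearson chi-square without continuity correction (chosen so z² equals
  the 2×2 chi-square statistic), paired t on change scores, and an
  independent t for between-cohort contrasts. Welch's correction is on by
  default for the independent t; a pooled-variance flag reproduces the
  classical test. No multiple-testing correction is applied anywhere.
* **Uncontrolled subgroup**: month-1 mean SBP strictly above 140 *and*
  month-1 mean DBP strictly above 90 ("more than 140 and 90" read as a
  conjunction of strict inequalities); a disjunctive variant
  (`combine="or"`), closer to guideline-style definitions, is available
  behind a flag.
* **Blood-pressure change** is month-1 mean minus month-5 mean, so a
  positive value is an improvement (pressure fell). Patients with zero
  transmissions in either month have no monthly record and are excluded
  from the paired analysis; the exclusion count is always reported.

## Transition analysis

Within-patient consecutive-day event pairs are pooled across patients in a
cohort (no pair spans two patients) and row-normalized into a 3×3 next-day
transition matrix; rows never observed are reported absent, not
zero-filled. From a matrix row, two conditional statistics follow:

* conditional adherence after state *s*: 100 − P(NT | s);
* conditional in-range share after *s*: 100 × P(IRT|s) / (P(ORT|s) + P(IRT|s)).

Published percent rows may sum to 99.9 or 100.1 after rounding; chain
arithmetic renormalizes rows, and comparisons against printed rows tolerate
±0.15 per cell.

The expected first-passage (hitting) time to the next in-range transmission
solves the standard linear system h = 1 + Q·h on the non-target states.
The system is restricted to states reachable from the start (the reachable
set is closed under transitions), which keeps it non-singular when an
off-path state is absorbing; a start state with positive probability of
entering a state that cannot reach the target has infinite expected hitting
time and is reported as an error. The empirical counterpart,
`mean_gap_to_in_range`, is window-censored: from-days with no subsequent
IRT in the patient's 150-day window are excluded from the mean and their
count is always reported, since censoring behavior is otherwise an
invisible analytic choice. The empirical gap and the analytic hitting time
agree only if the process really is a homogeneous first-order chain;
on real data they can legitimately differ, and both are reported.

## The synthetic cohort generator

The generator exists so that every downstream stage can be exercised, and
its estimators validated by parameter recovery, without any patient data.
It simulates the event process directly as a first-order three-state Markov
chain per cohort — the only dependence structure the analysis itself
estimates — rather than through a latent adherence-propensity model.

* **Events.** Each patient's day-1 event is drawn from the chain's
  stationary distribution (computed by linear solve) so short sequences
  carry no burn-in bias; subsequent days follow the cohort transition
  matrix. The default matrices are the published next-day tables (÷100,
  rows renormalized to sum exactly to 1).
* **Pre/post split.** A transmitting day is pre-deadline with probability
  `p_pre_given_transmit`, set from the printed rate pairs (0.749/0.913
  adherent, 0.390/0.580 nonadherent). A transmitting day that missed the
  deadline always has `call_attempted = true` (the call is what rescued
  it), so the generator never emits a late spontaneous transmission even
  though the file format permits one.
* **Reminder calls on missed days.** NT days receive a call with
  probability `p_call_given_miss`. Because calls are also forced on
  call-rescued days, the *observable* missed-call rate is
  (1 − p)·P(NT)/P(no pre-deadline transmission), not 1 − p; the defaults
  are therefore calibrated from the printed missed-call rates (1.02%
  adherent, 8.4% nonadherent), giving p ≈ 0.971 and 0.878.
* **Time effects.** The default chain is homogeneous: unit weekday
  multipliers and zero monthly decline, so the configured matrix and rates
  are recovered exactly in expectation. Two knobs depart from homogeneity
  when asked: `weekday_nt_modulation` scales the NT column per weekday
  (renormalized) to produce weekend dips, and `monthly_decline` lowers the
  transmission rate additively per 30-day month. The decline is
  implemented by thinning transmit days to NT with probability
  δ_m / (stationary post rate) *after* the chain runs: an NT-row
  perturbation of the chain would amplify through the stationary
  distribution (≈1.35× for the adherent matrix) and not recover the
  configured decline, whereas thinning is exact in expectation.
* **Vitals.** Each patient has latent month-1 means (SBP, DBP drawn from
  the cohort's between-patient distributions; pulse constant over time)
  and a latent improvement drawn from the configured change distribution;
  monthly means drift linearly from the month-1 value (raw month 2, the
  first post-washout month) to the month-5 value (raw month 6). Daily
  readings are drawn around the monthly mean (within-day SDs 8/6/8 mm Hg
  and beats/min), rounded to integers, and made consistent with the day's
  event label by rejection: IRT days redraw until all three rounded vitals
  are inside the patient's range; ORT days redraw from a widened normal
  (initial factor 2, escalating ×1.5 every 25 rounds under a 1000-round
  cap) until at least one rounded vital is strictly outside, with draws
  clipped to physical floors/ceilings that lie outside any legal alert
  range so clipping cannot destroy the label. Latent monthly means are
  clipped into the alert range with a small inset (min of the daily SD and
  a quarter of the range width) so in-range draws stay feasible for the
  rare patient whose latent mean drifts outside the range; in the default
  scenario this touches well under 1% of patients.
* **Alert ranges.** Each vital is personalized independently with
  probability 0.112, drawing wider bounds on a 5-unit grid inside the
  allowed limits (55–200 / 50–120 / 50–120).
* **Uncontrolled stratum.** An optional per-cohort fraction of patients
  has month-1 means above 140/90 (SBP ~N(152, 5) floored at 144, DBP
  ~N(96, 3) floored at 91.5) and its own larger configured improvement.
  Stratum members always receive widened personalized ranges; with
  default ranges, the IRT-day truncation at DBP 90 would drag their
  observed month-1 DBP means back under the screening threshold and make
  the strict-inequality subgroup selection noisy and biased.
* **Latent counterfactuals.** Every NT day carries a latent ORT/IRT label
  drawn from the chain's stationary transmitted split. This gives the
  unmet-need estimator an in-silico ground truth — the count of missed
  days that "would have been" out of range — which no real study has. By
  construction the latent split equals the estimator's homogeneity
  assumption, so this validates the estimator's arithmetic and plumbing,
  *not* the assumption itself.
* **Enrollment funnel.** The default scenario also generates 502
  short-record patients (30–179 monitored days, nonadherent dynamics) and
  768 enrolled patients with no monitored days, so eligibility filtering
  reproduces a 2093 → 823 funnel (39.32% eligible) and the funnel
  accounting in the run metadata is exercised.

Reproducibility: one seeded NumPy generator drives every draw in a fixed
order, so identical config + seed gives byte-identical CSV output; any
field change, including the seed alone, changes the output.

### What the generator does not emulate

The generated process is exactly first-order and (by default)
time-homogeneous. Real monitoring data exhibit weekend dips, slow
month-over-month decline, and empirical gaps to the next in-range
transmission longer than the first-order chain's hitting times — evidence
that the real process has longer memory. Passing parameter-recovery tests
therefore shows the estimators are correct for the model class they
assume, not that real data satisfy that class. Medication titration,
nurse-triage outcomes, dropout/disenrollment, and time-of-day deadline
behavior (everything below day resolution) are out of scope.

## Problem sizes and tolerances in the test suite

Recovery tests run at the full 475-patient adherent arm where the claim is
about the study scale (transition cell within ±1.5 points, pre-call rate
within ±1 point, SBP improvement within ±1 mm Hg — roughly 2–3 Monte-Carlo
standard errors at 475×150 patient-days), and at 150–400 patients
elsewhere with tolerances set the same way (≈3 standard errors at the
simulated size). The analytic hitting time is checked against a 10⁶-step
simulated chain within 1%; type-I error of each statistical test is
checked at 5% ± 1.5% over 10,000 null replicates. The default full
scenario (2093 patients, ~200k patient-days) generates in about a second,
so the end-to-end pipeline tests run it directly.

## Known limitations

* The unmet-need estimator inherits the assumption that the out-of-range
  fraction of transmitted days applies to missed days; the transition
  matrices themselves show next-day in-range shares differ after missed
  days, so this is an approximation the package reports but cannot fix.
* The observed missed-call and "no transmission after call" percentages are
  structural consequences of the generator's call model (calls never
  rescue NT days; rescued days always had calls) and will not match every
  program's operational reality.
* Monthly decline thinning breaks exact first-order structure on converted
  days; with nonzero decline, transition-matrix recovery is approximate.
* `bp_change_analysis` compares exactly two months; repeated-measures or
  mixed models over all five months are deliberately out of scope.
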