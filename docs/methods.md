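# Methods

This note documents the models, the parameter derivations, the numerical
conventions, and the design choices that were genuinely open. Currency is
PLN (public payer, no FX conversion; ~4.5 PLN per euro at the time the
source estimates were made). No empirical claim here goes beyond what the
test suite and `scripts/acceptance.py` compute.

## Population and comparison

The modelled cohort is adult post-stroke patients with dysphagia who
tolerate semisolid intake but aspirate fluids (Gugging Swallowing Screen
band 10–14). The intervention is a xanthan-gum thickener added to all
fluids; it is assumed to remove fluid aspiration without shortening or
lengthening the dysphagia itself. The comparator is routine clinical
practice (postural/behavioural compensation), under which patients keep
aspirating. Outcomes are QALYs and direct payer costs; the decision
statistic is the ICUR, judged against the Polish threshold of
147,024 PLN/QALY.

## Static model

A fixed 8-week dysphagia course with at most one aspiration-pneumonia (AP)
episode per patient, evaluated in closed form (see `static_model`). The
arm asymmetry carries the whole treatment effect: the intervention arm
uses the non-aspirators' observed AP risk (1/57 ≈ 1.75 %) and utility
(0.37), the comparator the aspirators' (10/82 ≈ 12.2 %, utility 0.15). AP
costs 1924 PLN per episode and subtracts 0.13 utility for 2/52 of a year.
Conventions that matter:

* AP risks enter as the raw fractions 1/57 and 10/82, not their rounded
  percentage forms — rounding first shifts the ICUR visibly.
* Thickener purchase is pro-rated to fractional tins
  (37.96 g/day × 56 days ÷ 175 g × 77.05 PLN = 935.94 PLN). The patient
  copayment (3.20 PLN/tin) is excluded from the payer perspective.
* No monitoring cost and no discounting over the 8-week horizon.
* When the QALY difference is zero the ICUR is reported as undefined; when
  one arm is both cheaper and more effective a dominance flag replaces the
  ratio.

## Parameter estimation

* **Rates.** Cumulative risk over a follow-up converts to a weekly
  incidence rate by `IR = −ln(1 − CR)/T` (constant hazard); pooling across
  studies is a patient-weighted mean of per-study rates. The pooled weekly
  baseline AP rate in patients without dysphagia is 0.4036 %.
* **Relative risks.** From 2×2 counts, the point estimate is the risk
  ratio and the CI is the Katz log-normal interval with
  `SE = sqrt(1/a − 1/n1 + 1/b − 1/n2)`. The counts 24/83 and 15/155 vs
  5/143 give RR 8.27 (3.28–20.85) for dysphagia with aspiration and 2.77
  (1.03–7.42) without, relative to no dysphagia.
* **Rate × RR → probability.** Treatment effects apply on the hazard
  scale: `p = 1 − exp(−IR·RR)`. At these magnitudes this is numerically
  indistinguishable from multiplying probabilities.
* **Resolution schedule.** Dysphagia prevalence anchors (fractions still
  dysphagic at given days post stroke) are interpolated linearly onto the
  weekly grid (week *w* ↔ day 7*w*; the 52nd cycle absorbs the day-365
  anchor) and differenced conditionally:
  `r_w = 1 − prev(w)/prev(w−1)`, clamped to [0, 1]. A zero-prevalence
  anchor at one year is appended when absent, encoding full resolution
  within a year. Re-simulating the schedule without mortality reproduces
  the anchors exactly (round-trip property-tested).
* **Mortality.** Weekly death probabilities are piecewise constant:
  4.60 % (weeks 1–4, covering the first 30 days), 0.96 % (weeks 5–13,
  days 31–90), 0.24 % thereafter — nearest whole weeks covering the
  day-denominated intervals, since the model cycles weekly. The implied
  52-week survival is (1−0.046)⁴(1−0.0096)⁹(1−0.0024)³⁹ = 0.6915. A
  scenario alternative fits cumulative mortality as `a·ln(t) + b` by
  ordinary least squares on (ln t, mortality) and differences the fitted
  curve into conditional weekly probabilities.
* **Deterioration.** The weekly probability that a non-aspirating patient
  starts aspirating is taken directly as 0.0011; the underlying cohort
  (3/120 over six months) does not pin down the authors' exact
  week-counting convention, so the value is treated as an input rather
  than re-derived.
* **Distributions for PSA.** Standard deviations are back-calculated from
  95 % intervals (`SD = width/(2·1.95996)`); Beta shapes follow by method
  of moments; ratio parameters get log-normal distributions matched to
  their CIs; binomial risks are drawn Beta(events, n − events); costs are
  gamma with SD = 20 % of the mean (an assumption — the source's PSA
  appendix is not public).

## Markov cohort model

Weekly cycles over 52 weeks; states: no dysphagia, dysphagia without
aspiration, dysphagia with aspiration, a two-week AP tunnel tagged by the
originating dysphagia state, and death (absorbing). Choices that were
genuinely open, and how they were settled:

* **Starting states.** The comparator cohort starts (and, absent
  resolution, stays) in dysphagia-with-aspiration (AP RR 8.27); the
  intervention cohort starts in dysphagia-without-aspiration (RR 2.77,
  utility 0.37), mirroring the static model's arm asymmetry.
  Deterioration (0.0011/week) moves intervention patients to the
  aspirating state — treatment failure. Comparator patients cannot
  spontaneously stop aspirating.
* **Competing risks** apply in the order death → AP onset →
  resolution/deterioration, with survivors split multiplicatively; every
  row of every transition matrix is checked stochastic to 1e−9.
* **Tunnel.** AP lasts exactly two weeks (ten days of antibiotics plus
  recovery); resolution and deterioration are suspended inside it, and
  week 2 returns the patient to the originating dysphagia state. Death
  inside the tunnel scales the weekly baseline hazard by RR 2.99, capped
  at 1. Patients in the tunnel still have dysphagia: they keep consuming
  thickener and count for monitoring.
* **Accrual convention.** Continuous quantities — utilities, the weekly
  thickener cost (116.99 PLN, intervention arm only), monitoring visits
  (186 PLN at weeks 1, 4, 12, 26, 39, 52, charged to dysphagic occupants
  in both arms) — accrue on start-of-cycle occupancy, with no half-cycle
  correction and no discounting over the one-year horizon. The AP episode
  cost (1924 PLN) is an event cost charged on each tunnel entry. The
  start-of-cycle convention is what makes the published component
  magnitudes coherent: ~5 person-weeks of thickener (≈583 PLN) including
  the entry week, and ~1.8 of 6 monitoring visits with the week-1 visit
  seeing the full cohort.
* **Validation.** In the degenerate configuration (8-week horizon, no
  mortality/resolution/deterioration, per-week AP hazard calibrated so the
  engine's expected 8-week episode count equals the static risks 1/57 and
  10/82), the cohort engine reproduces the static model's QALYs and costs
  within 1 %. The episode-count matching is needed because the cohort
  engine admits pneumonia recurrence while the closed-form model counts at
  most one episode per patient — with a first-episode-matched hazard the
  comparator AP cost differs by ~3 % for exactly that structural reason.

### Placeholder inputs (flagged in the fixture)

Two dynamic-model inputs were published only in supplementary material and
are shipped as reverse-engineered placeholders, marked `assumed` in
`base_case.yaml` and surfaced by `ModelConfig.assumed_fields`:

* prevalence anchors 1.0 / 0.53 / 0.27 / 0.07 at days 0 / 7 / 28 / 180 —
  a typical post-stroke dysphagia natural history (roughly half resolve in
  the first week, under a tenth still dysphagic at six months);
* no-dysphagia utility 0.49, chosen once so the base-case QALYs land near
  the published 0.351/0.331 (the shipped fixture gives 0.353/0.322).

With these placeholders the dynamic base case prints an ICUR of
14,390 PLN/QALY — the same order as the published 20,977 and far below the
threshold, but not a reproduction: the published AP-cost components imply
roughly 23 % less pneumonia exposure per dysphagia person-week than the
stated hazards generate under this structure, a convention the public text
does not determine. The Markov engine is therefore validated through the
structural properties above rather than through its base-case numbers, and
the acceptance script reports only static-model quantities.

## Sensitivity analysis

* **One-way (tornado).** Each uncertain parameter is pushed to its bounds
  with everything else at base. Printed bounds are used where they exist
  (utility 0.15 in 0.135–0.165, utility 0.37 in 0.32–0.42, AP decrement
  0.10–0.15, the RR CIs); the static AP risks, which have counts but no
  printed interval, use exact Clopper–Pearson 95 % CIs. Rows are sorted by
  descending ICUR span, ties broken by name. At extreme comparator
  pneumonia risk the intervention becomes dominant; such rows report an
  undefined ICUR rather than a number.
* **Scenarios.** Multi-parameter overrides plus switches: monitoring
  on/off, AP cost variants (halved/doubled), the log-fit mortality source,
  and a life-years-only mode (all living-state utilities 1, AP decrement
  0).
* **PSA.** Parameters are drawn independently per iteration (no
  correlation structure is assumed) from the distributions above;
  10,000 iterations by default, fully reproducible from one seed. The
  CEAC reports, at each willingness-to-pay λ, the fraction of draws with
  net monetary benefit `λ·ΔQALY − ΔCost ≥ 0`.

## What the synthetic generators do and do not emulate

`simulate_two_by_two` draws binomial 2×2 tables at stated group risks, and
`simulate_prevalence` produces prevalence trajectories implied by a known
resolution schedule (exact, or with binomial sampling noise). They
reproduce the sampling structure the estimation formulas assume —
independent binomials, constant hazards within follow-up — so passing
round-trip and recovery tests shows the formulas are implemented
correctly, not that real cohorts satisfy those assumptions (real studies
have losses to follow-up, competing mortality during follow-up, and
non-constant hazards that these generators deliberately omit).

## Problem sizes and numerics

The default test suite runs the cohort engine at horizons of 8–52 weeks
(8 states, so a full year is a 53×8 occupancy array), the PSA at
2,000–10,000 iterations and the acceptance script at 10,000; Beta-moment
recovery is checked with 10⁶ draws. Everything is exact arithmetic or
vectorised numpy; occupancy conservation is asserted at 1e−10 and
calibration round-trips at 1e−9.

## Known limitations

* Cohort-level (not patient-level) modelling: no memory beyond the
  two-week tunnel, no age/sex stratification.
* The dynamic base case depends on two placeholder inputs (above); its
  absolute numbers are indicative.
* RR intervals are large-sample log-normal; no exact or mid-P intervals.
* No EVPI/EVPPI, no correlated PSA draws, no structural averaging across
  the two models.
* Longer horizons extend the schedules with their terminal values; no
  extrapolation model beyond one year is fitted and no discounting is
  applied (immaterial at one year, a limitation for longer horizons).
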