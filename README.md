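# dyscue

Cost-utility models of xanthan-gum food thickening (vs routine clinical
practice) in adult post-stroke dysphagia, from the Polish public-payer
perspective.

## The problem

Roughly 37–78 % of stroke patients develop dysphagia. Patients who tolerate
semisolids but aspirate fluids (Gugging Swallowing Screen 10–14) face a
sharply elevated risk of aspiration pneumonia (AP) and death. Thickening
fluids with a xanthan-gum product removes fluid aspiration without changing
how long the dysphagia itself lasts. `dyscue` asks whether paying for the
thickener is good value: it computes the incremental cost-utility ratio

```
ICUR = (C_intervention − C_comparator) / (QALY_intervention − QALY_comparator)
```

in PLN per quality-adjusted life year, with two models of the same
comparison:

* **Static model** — a closed-form 8-week course. Per arm,
  `C = C_thickener + C_AP · p(AP)` and
  `QALY = U · 8/52 − ΔU_AP · 2/52 · p(AP)`, where the intervention arm uses
  the non-aspirators' pneumonia risk (1/57) and utility (0.37) and the
  comparator the aspirators' (10/82, 0.15).
* **Markov cohort model** — a 52-week weekly-cycle simulation with
  dysphagia resolution, deterioration (onset of aspiration), a two-week
  aspiration-pneumonia tunnel, piecewise post-stroke mortality, and
  scheduled monitoring visits.

Around the models sit a parameter-estimation layer (cumulative risk → weekly
incidence rate, relative risks with log-normal CIs from 2×2 counts,
prevalence-anchor calibration of the weekly resolution schedule,
back-calculated Beta/log-normal/gamma distributions) and deterministic
(tornado, scenario) and probabilistic sensitivity analysis with
cost-effectiveness acceptability curves. A `synthetic` module provides the
base-case parameter fixture and seeded generators for round-trip testing.

Intended users: health economists and HTA analysts reproducing or adapting
the analysis, and anyone who wants a small, fully tested reference
implementation of a two-model cost-utility study.

## Worked example

```
$ cue synth config --out cfg.yaml      # write the base-case configuration
$ cue run --config cfg.yaml --model static
model: static
QALY  intervention=0.0568 comparator=0.0225 incremental=0.0344
cost  intervention=969.70 comparator=234.63 incremental=735.06
ICUR: 21,388 PLN/QALY
```

The thickener course costs 935.94 PLN (37.96 g/day for 56 days from
175 g tins at 77.05 PLN), pneumonia treatment adds 33.75 PLN expected cost
in the intervention arm vs 234.63 PLN in the comparator, and the utility
gain of removing aspiration (0.37 vs 0.15 over 8/52 of a year) yields
0.0344 incremental QALYs — about 21,400 PLN per QALY, far below the Polish
threshold of 147,024 PLN/QALY.

```
$ cue psa --config cfg.yaml --n 10000 --seed 1
iterations: 10000  seed: 1
P(cost-effective at 147,024 PLN/QALY) = 1.0000

$ cue dsa --config cfg.yaml --model static
                 parameter  icur_at_low  icur_at_high         span
    static.u_no_aspiration 27555.301578  17476.302675 10078.998902
    static.p_ap_aspirators 25078.582321  16085.923888  8992.658433
...
```

The tornado shows the result is most sensitive to the utility gained by
removing aspiration; even at its pessimistic bound the ICUR stays below
28,000 PLN/QALY.

The dynamic model runs the same way (`--model dynamic`). Two of its inputs
— the dysphagia-prevalence anchors driving the resolution schedule and the
no-dysphagia utility — have no published base value; the shipped fixture
carries clearly flagged placeholder values (see `docs/methods.md`), so its
output is indicative rather than a reproduction.

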