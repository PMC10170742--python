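# uwcager

Quantitative umbilical-wound-class (UWC) age estimation for neonatal
viviparous sharks, built around the mark-recapture study of blacktip reef
sharks (*Carcharhinus melanopterus*) at Moorea, French Polynesia.

Viviparous shark neonates carry an open umbilical wound that heals over the
first ~5 weeks of life. Because the healing trajectory is predictable, wound
size is a non-lethal clock for the relative age of a neonate. This package
implements that clock end to end, for field ecologists who have capture
records (dates, traced wound area and perimeter, morphometrics) and want
relative ages, an ordinal wound-class scheme, a validated error rate, and a
back-calculated parturition season.

## The model

Two mixed-effects healing regressions are fitted to recaptured "time zero"
neonates (sharks first caught with umbilical-cord remnants, anchoring them
at age 0), with shark identity as a random intercept:

- wound area (quadratic decline):  √A = a₀ − a₁·√t,   so  A(t) = (a₀ − a₁√t)²
- wound perimeter (linear):        P(t) = b₀ − b₁·t

with t the age in days. The Moorea estimates are a₀ = 0.311, a₁ = 0.053,
b₀ = 1.299, b₁ = 0.037; the curves reach zero at 34.4 d (area) and 35.1 d
(perimeter), so wounds close completely by day 36. Evaluating the curves at
12 and 24 d gives the critical values A* = 0.016 cm² and P* = 0.41 cm that
define four classes:

| UWC | age (days) | area (cm²) | perimeter (cm) |
|-----|-----------|------------|----------------|
| 1   | 0–12      | > A*       | > P*           |
| 2   | 12–24     | ≤ A*       | > P*           |
| 3   | 24–36     | < A*       | ≤ P*           |
| 4   | ≥ 36      | 0          | 0              |

Inverting the curves gives per-event ages, t = ((a₀−√A)/a₁)² and
t = (b₀−P)/b₁ (means of both are used); recaptures validate the scheme by
comparing the predicted elapsed time between captures (pTAL) with the actual
time at liberty (TAL). Parturition dates are back-calculated by subtracting
the class midpoint age (6, 18 or 30 d) from the first capture date, and body
condition is tracked across classes with Fulton's K = 10⁵·M·PCL⁻³.

A fully-tested synthetic cohort generator (`uwcager.simulate`) reproduces
the statistical structure of the field data — per-shark random intercepts,
measurement noise on the transformed scales, a smooth September–January
birth pulse with the published month probabilities, the published
morphometric distributions and the ~8.5% recapture rate — so every stage is
testable without the field deposit.

## Worked example

```
$ uwcager simulate --seed 42 --n-sharks 800 --out cohort.csv --truth truth.csv
wrote 909 events for 816 sharks to cohort.csv

$ uwcager fit --in cohort.csv --out fit.json
a0=0.2552 a1=0.0422 b0=1.2407 b1=0.0363 closure=37 d

$ uwcager classify --in cohort.csv --fit fit.json --out labeled.csv
counts: UWC1=274, UWC2=196, UWC3=271, UWC4=168

$ uwcager validate --in cohort.csv --fit fit.json --out validation.csv
|TAL - pTAL| = 4 ± 3 days (raw 3.84 ± 3.04; n = 46; 44 excluded)

$ uwcager parturition --in labeled.csv --fit fit.json --out births.csv
692 births (124 skipped, 0 outside window); chi2 = 357.77, df = 4, p = 3.69e-76
```

Reading the output: the fitted intercepts sit below the generating values
(0.255 vs 0.311) because the cord-remnant anchor treats sharks that are
really 0–2 days old as age 0 — an approximation inherited from the field
protocol (see `docs/methods.md`). The validation line is the headline
accuracy: predicted and actual times at liberty differ by 4 ± 3 days here,
the same scale as the 5 ± 3 days reported for the field classification
(sharks used for fitting, or with a healed wound at either capture, are
excluded — the "44 excluded"). The parturition line rejects a uniform birth
season (χ², df = 4): births are strongly pulsed, peaking in
October–November. `uwcager run --in cohort.csv --out-dir out` chains all
stages and writes `summary.json` plus per-stage CSVs.

The shipped `uwcager.datasets.load_field_validation()` returns the 17
published capture/recapture validation records; their |TAL − pTAL| column
summarises to 4.88 ± 3.08 days, i.e. the published 5 ± 3.

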