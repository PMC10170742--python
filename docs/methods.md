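# Methods

This note records the statistical model the package implements, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate about real field data.

## Healing regressions

Umbilical wound size is modelled on the scales where healing is linear:

- √area = a₀ − a₁·√t + u_i + ε   (area "quadratic decline" on the raw scale)
- perimeter = b₀ − b₁·t + v_i + ε′

with t the age in days and u_i, v_i per-shark random intercepts. Estimation
is restricted maximum likelihood (statsmodels `MixedLM`, convergence
tolerance 1e-8); when the random-intercept variance estimate degenerates to
zero, or the optimiser fails, the fit falls back to ordinary least squares
and records the fallback in the fit metadata (`method_area`,
`method_perim`). Random slopes are not used: with at most three
observations per shark they are not identifiable. The default coefficients
throughout (a₀, a₁, b₀, b₁) = (0.311, 0.053, 1.299, 0.037) are the
published Moorea estimates (cm and day units; √area in √cm²).

Exclusions from fitting. Closed wounds, recorded as exactly (0, 0), are
excluded from the response: the linear predictors are unbounded below, and
zero-truncated observations would otherwise attenuate the slopes. The same
logic extends to a single response that is unmeasurably small (≤ 1e-6)
while the wound is still open — such a value pins the curve tail at zero.
These rows are counted, never silently dropped.

Age-0 anchoring. Training histories are anchored by umbilical-cord
remnants: the first capture is assigned age 0 even though remnants persist
for a day or two. Because √t is steep near zero this biases the fitted
intercepts downward by roughly a₁·E[√t_anchor] (≈ 0.04 on the √area scale
for 0–2-day anchors) — visible in pipeline runs on synthetic cohorts. The
bias largely cancels in time-at-liberty differences, which is why the
validation error is unaffected; analyses needing unbiased intercepts should
anchor with sharks of exactly known age.

## Classification

Critical values are the area curve at the first class boundary (12 d) and
the perimeter line at the second (24 d): 0.016 cm² and 0.41 cm for the
default fit (rounded for reporting; comparisons always use the unrounded
values). Perimeter decides the 24-day boundary first, then area separates
the first two classes: area ranges overlap between the middle classes in
the field data, so area alone cannot place an event. Ties at the critical
area go to UWC2. The off-table combination (area above critical, perimeter
at or below critical) is assigned UWC3 and flagged inconsistent rather than
rejected, keeping classification total on all physically possible wounds.
The closure day is the ceiling of the larger x-intercept (35.1 d → 36 d);
UWC4 (healed) is treated as age ≥ 36 d.

## Age inversion and validation

The inversions t = ((a₀−√A)/a₁)² and t = (b₀−P)/b₁ are clamped at zero: the
area inversion squares a difference, so a wound larger than the age-0
intercept would otherwise return a spurious positive age from the
unphysical branch. The combined age is the unweighted mean of the two
estimates (no published variance components exist to weight them). Closed
wounds are censored — age is only bounded below by closure — and censored
events propagate exclusion rather than an imputed age. Validation
(pTAL vs TAL) uses the first and last capture of each recapture history and
excludes training-set sharks and censored events, each with an explicit
reason.

## Parturition back-calculation and seasonality

A neonate's birth date is its first capture date minus the midpoint age of
its class interval — 6, 18, 30 d for the default boundaries. Dates are
absolute ordinal days, so January captures back-calculate into December of
the prior year. Juveniles (UWC4) are skipped and counted. The monthly
distribution is tested against a uniform expectation over the season window
(September–January by default) with a Pearson chi-square; back-calculated
dates falling just outside the window (e.g. an early-September capture of a
young class mapping into August) are counted and logged.

The midpoint rule discretises age to the class centre, so individual birth
dates carry a ±6-day error even with perfect classification. This error is
unavoidable in the method; what the package's tests establish is that it
does not distort the *monthly distribution* (see below).

## Body condition

Fulton's K = 10⁵·M·PCL⁻³ (mass in kg, precaudal length in cm; ≈ 1.2–1.4
for a well-conditioned neonate). Group comparisons follow the field
protocol: a Shapiro–Wilk screen per class with W < 0.90 flagged (reported,
but not gating the ANOVA, which the protocol ran regardless), one-way
ANOVA, and Tukey HSD at family α = 0.05. Groups with fewer than two records
are excluded with a warning. Sex is ignored: neonatal morphometrics show no
sex difference in this species.

## Synthetic cohort generator

The generator emulates one parturition season of the gillnet survey:

- Cohort design: a "time zero" subcohort of days-old neonates deliberately
  recaptured (defaults 13 once, 3 twice — the field training design), plus
  a survey cohort (default 500 sharks) captured once at an age uniform over
  a 45-day window and recaptured with probability 0.085 after a 7–28 day
  delay. Capture ages within the window are uniform (the field age
  distribution is unknown); the window yields roughly one fifth of events
  in the healed class.
- Ages are continuous: birth instants sit at a uniform sub-day offset
  within the birth date, so the true age at a capture is the whole-day date
  difference plus (offset − ½), and a shark cannot be caught before it is
  born. Without this, integer ages make the class-midpoint back-calculation
  systematically half a day early, which is detectable as a September
  surplus at large n.
- Wound observations: noise is applied on the transformed scales (√area,
  perimeter), as per-shark random intercepts (SDs 0.018, 0.07) plus
  measurement error drawn from a mean-preserving symmetric truncated normal
  on (0, 2μ) (SDs 0.038, 0.24). Symmetric truncation keeps the conditional
  mean exactly on the healing curve at every open age — an asymmetric clamp
  at zero would bias the fitted slopes even asymptotically — at the price
  of measurement spread shrinking as the wound vanishes, which is also how
  tracing error behaves. Closure is a state, not a measurement: a wound is
  closed from the first whole day at or after the larger of the
  individual's two noise-free x-intercepts, and closed wounds are exactly
  (0, 0); where one curve reaches zero while the other keeps the wound
  open, that measurement collapses to an infinitesimal positive floor.
- Noise calibration: the study reports no variance components, so the four
  SDs were tuned once (`scripts/calibrate_noise.py`) against two pipeline
  targets — an end-to-end mean |TAL − pTAL| inside the 3–7 day band around
  the published 5 ± 3 days (defaults give ≈ 4.3 d), and 10% recoverability
  of all four fixed effects from a 200-shark tracked cohort. The two
  targets pull the SDs in opposite directions; the defaults sit where both
  hold, in the lower half of the validation band.
- Birth season: months are drawn from the published multinomial
  (5.2/32.7/41.3/17.6/3.2% over Sep–Jan); days within a month come from a
  smooth (C¹) daily intensity built as cubic smoothsteps between month-edge
  values solved so every month integrates exactly to its probability, with
  zero slope at every month boundary. A month-block-uniform daily density
  jumps at calendar-month edges — which no biological birth pulse does —
  and those jumps interact with the ±6-day midpoint error to inflate small
  months adjacent to large ones (September by ~30%), an artefact of the
  block model rather than of the method. For a smooth intensity the
  month-mass change under symmetric smearing is proportional to the slope
  difference at the month's edges, hence ~zero by construction.
- Morphometrics: precaudal length ~ N(41.7, 2.0) cm at birth growing
  0.03 cm/day; mass = K·PCL³/10⁵ with K declining linearly from 1.25 at
  birth to 1.05 at 60 d (floor thereafter) plus N(0, 0.1) noise. The K
  slope is illustrative — chosen only to make the body-condition decline
  across classes detectable — not an estimate.

## What the synthetic tests show — and don't

Passing tests establish that the pipeline is internally correct: exact
coefficient recovery and exact age/label/pTAL recovery at zero noise, 10%
coefficient recovery and a field-scale validation error at the calibrated
noise level, and an unbiased back-calculated birth season at n = 5000. They
do not establish that real wounds follow these curve families, that real
measurement error is homoscedastic on the transformed scales, or that real
capture ages are uniform; nor do they reproduce real-data sample counts or
ANOVA statistics, which require the original field deposit. Temperature
effects on healing rate, spatial site structure and mortality are outside
the generator's scope.

## Numerical conventions

Problem sizes used by the default test run and the acceptance script:
50 replicates of 200 tracked sharks for parameter recovery, 20 seeds of
1500-shark cohorts for the validation band, 100 seeds of 5000-shark cohorts
for seasonality recovery, 30 replicates each at 50/200/800 sharks for the
bias trend. Dates parse as dd/mm/yyyy by default (configurable). Missing
fields are skipped and counted at every stage; nothing is imputed.
Fractional class midpoints are rounded to whole days before date
subtraction (dates have daily resolution). Random streams derive from a
single integer seed per cohort; identical configurations are bit-identical.
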