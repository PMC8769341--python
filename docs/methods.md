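# Methods

This note records the model behind the synthetic generator, the
conventions adopted where the published snapshot format leaves the
semantics open, the numerical choices in the statistical routines, and
what the test suite's results do and do not establish.

## The data model

An *incarceration episode* is one admission-to-discharge stay of one
individual; a person may have many episodes. The portal publishes
three projections of the episode history:

* **ADS** — one row per admission on or after the coverage start
  (default 2014-01-01), discharge blank while the stay is ongoing;
* **DDS** — one row per completed episode, regardless of when the
  admission happened, plus the individual's age at discharge in
  integer years;
* **current roster** — the episodes in custody on the *data date*
  (the scrape date, default nine days after the coverage window ends).

The pipeline's contract is that on anomaly-free inputs the
ingest → reconcile → merge → clean chain is the exact inverse of this
projection: the final episode table equals the truth table on keys,
durations and demographics. The test suite enforces this round trip
at n ≈ 20,000 episodes.

## Synthetic generator

Per person: a first admission drawn over the admission window with
weekday weights (admissions dip at weekends, matching the weekly
rhythm of real jail data; an optional year-end admission dip is
available but off by default, since the cause of such dips in real
data is unestablished); a birth date placing the age at first
admission on a truncated normal (mean 35.3 y, sd 12, range 16–85 —
the mean is set below the 37-year target for the mean age *at
discharge* because repeat admissions age the population); gender
female with probability 0.090; race Black/Asian/missing with
probabilities 0.54/0.015/0.445 (the portal's race coding supports no
finer analysis, so neither does the generator).

Stay lengths come from a three-component exponential mixture
(component means 2/30/250 days before rescaling, weights
.35/.45/.20) truncated at five years. Status codes are drawn from a
simplex over {CS, CSP, DE, DEP, DNS, DPV, SCO, SSR} with a 6% missing
rate; the SSR (sentenced state-ready) group's stays are scaled ×6 to
plant the long-stay subgroup visible in real cap-sweep breakdowns.
Because multipliers and truncation would otherwise distort the overall
mean, a global scale factor is solved by bisection on the closed-form
truncated-exponential mean so that the population mean stay equals the
configured 64 days exactly in expectation.

Readmission is generated sequentially: after each discharge the person
continues to another admission with probability
`sigmoid(base + s·duration [+ log-odds offsets])`, where the base is
centred so the mean episodes per person is the configured 2, and
`s = −0.002` per day makes longer stays independently less likely to
be followed by a same-year readmission. The gap to the next admission
is exponential with mean 120 days.

**Focus-week policy planting.** The planted 2020-03-23 policy has
four dials: `extra_discharges` picks episodes spanning the whole week
and truncates their discharge into it — these are by construction
long-serving individuals, so the census drops and the cohort's
durations lengthen through the same mechanism the real policy used;
`duration_multiplier` back-dates the admission of episodes already
discharging in the week; `readmission_odds_multiplier` scales the
continuation odds after an in-week discharge; `age_shift_years` makes
individuals with an in-week discharge older by shifting their birth
date. Defaults are all neutral; the acceptance scenario uses
100 extra discharges, odds ×0.5, age +2 y at roughly 35,000 episodes.

**Corruption and ledger.** Eighteen anomaly classes mirror the
removal, merge and cleaning categories. Injection targets are drawn
on *disjoint individuals*, so each anomaly's downstream effect is
independent and exactly predictable from the ledger; the ledger
records the class, the truth episode, the snapshot, the final row
position and the touched field of every injection. Two classes
deliberately keep the recorded age consistent with the (corrupted)
dates — the multi-year duration outlier and the pre-window admission
shift — so that they are pure date anomalies and do not leak into the
age-cleaning counts. Knock-on effects that are intrinsic to the
pipeline are embraced rather than hidden: removing a DDS row (cross-
file conflict, conflicting pair, clerical omission) necessarily turns
its surviving ADS partner into a category-5 acceptance, and the tests
assert that arithmetic exactly.

What the generator does **not** model: seasonal or COVID-era admission
dynamics, court processing, bail status, racial disparity structure,
transgender identity, or any behavioural response to policy. Passing
tests show the pipeline recovers a truth *of this structure*; they do
not validate substantive conclusions about any real jail system.

## Conventions where the format is silent

* **Inversion threshold.** Discharges more than one calendar day
  before the admission are removed at reconciliation; same-day and
  previous-day inversions are clock slips repaired during cleaning to
  a discharge at 23:59 on the admission day with a half-day duration.
  Publishing practice mixes both behaviours, and this split reconciles
  them deterministically.
* **Conflicting discharge groups** (same id and admission, different
  discharges, within DDS) are removed entirely: with no principled
  tie-break, keeping one member would fabricate data. Exact duplicate
  rows are deduplicated in both tables (keep one), not only in ADS, so
  the one-row-per-key invariant survives arbitrary inputs.
* **Census membership is half-open**: a person counts from the
  admission date up to but not including the effective discharge date
  (ongoing stays run to the data date). This makes census-sum and
  clipped-duration-sum person-days identical — an identity the tests
  check exactly — and a same-day stay contributes no census days. The
  half-day convention applies to the *duration* variable only.
* **Weeks run Monday–Sunday**, so March 23–29 of 2020 is one week;
  the weekly net change is Sunday-census minus previous-Sunday-census
  and telescopes to the endpoint difference.
* **Implied birth dates use the interval midpoint** `discharge −
  (age + 0.5) yr`, unbiased under a uniform-birthday assumption for
  integer-truncated ages; years are 365.25 days wherever a year unit
  is needed. The least-squares imputed birth date is the arithmetic
  mean of the implied dates. A single record whose recomputed age
  moves by more than five years poisons all of that individual's age
  data.
* **Readmission is episode-level and strictly-after**: each discharged
  episode is one observation, and a readmission requires an admission
  strictly after the discharge with an admission date in the same
  calendar year. Person-level deduplication is deliberately not
  applied.
* **Cap semantics**: caps are whole days ≥ 1; ongoing episodes are
  measured to the data date before capping; episodes excluded by the
  five-year rule stay excluded from the sweep. The default grid
  {1, 2, 3, 5, 7, 14, 30, 60, 100, 180, 365, 730, 1826} covers one
  day to five years roughly log-uniformly.

## Numerical choices

* **Logistic fits**: IRLS (Newton) with step halving, so the deviance
  is non-increasing across accepted iterations; convergence when the
  largest coefficient update falls below 1e-8, at most 100 iterations;
  linear predictors clipped at ±35 for overflow safety; standard
  errors from the inverse observed information; perfect separation is
  raised as an error, never silently returned. The implementation is
  cross-checked against an independent GLM fitter to 1e-6 in the test
  suite.
* **One-sided KS**: the statistic is evaluated over all pooled sample
  points (ties handled by right-continuous ECDFs); the asymptotic
  p-value `exp(−2mD²)` is the default, and an O(n_a·n_b) exact
  lattice-path p-value is available for tie-free samples (used in
  tests up to n = 25, validated against permutation Monte Carlo).
* **Degenerate inputs**: empty KS samples, empty cohorts, windows
  beyond the data date, sub-day caps, and configs naming both real
  and synthetic inputs are rejected with named errors; an empty
  episode table produces an all-zero census.
* **Determinism**: one pipeline seed fans out to the generator and
  the corruptor by fixed offsets (kept below 2³¹); reruns of the same
  config are byte-identical, and the manifest's config hash covers the
  analytic configuration but not the output location.

## Problem sizes

The test suite runs the round trip at ~20,500 episodes, ledger
equivalence at ~11,500, the logistic recovery at 300,000 observations
plus 100 replicates of 20,000, and the policy scenario at ~35,000
episodes; the acceptance script uses ~28,000 final episodes. These
sizes give the statistical checks comfortable power (e.g. the planted
interaction is detected at α = 0.05 in ≥ 95/100 replicates) while the
whole suite completes in well under a minute of compute per heavy
test.

## Known limitations

* Exact recovery of recorded ages is guaranteed only for individuals
  whose records imply a single common birth date; for merely
  *compatible* (interval-overlapping) records the mean-of-midpoints
  estimator can land outside the intersection in adversarial
  configurations, though on generator-distributed data the mean
  absolute change is far below one year.
* Record linkage is exact-key only; near-miss keys (admission times
  differing by minutes across files) are not matched, mirroring the
  source format's own behaviour.
* The readmission models are associational; no causal claim is
  licensed by the fits, and the synthetic generator's readmission
  mechanism is a convenience, not a criminological model.
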