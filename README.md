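# jailstint

Reconstruction and counterfactual analysis of jail admission/discharge
records, modelled on the open-data publishing pattern of the New York
City jail system.

## The problem

Many large jail systems publish their history as two separate snapshot
tables — an **admissions** table (ADS) and a **discharges** table (DDS)
— plus a daily **current-custody roster** that is overwritten every day
and never archived. None of the three is a usable longitudinal record
on its own: the files overlap, disagree, contain exact and
near-duplicate rows, inverted date-times, impossible ages, and
individuals whose demographics change between rows. Researchers who
want to know *how many people were in jail on a given day*, *how long
people stay*, or *what a length-of-stay cap would have done* must first
reconcile the three files into a single table of incarceration
episodes.

`jailstint` implements that reconstruction as a tested, reusable
pipeline, together with the downstream analyses it enables:

1. **ingest / reconcile** — read the snapshot CSVs and remove four
   categories of irreparable records (exact duplicates; discharge-table
   groups that conflict on the discharge date-time; discharges more
   than a day before their admission; cross-file discharge conflicts);
2. **merge** — accept records into an episode table through seven
   match categories across ADS, DDS and the current roster, each input
   row consumed at most once;
3. **clean** — resolve per-person demographics by unique mode, resolve
   per-episode status/charge conflicts, impute a least-squares birth
   date from inconsistent integer ages at discharge, and derive the
   stay duration on calendar dates (same-day stays count one-half day;
   stays above five years are excluded as clerical errors);
4. **census** — reconstruct the daily population headcount and its
   weekly (Monday–Sunday) net changes with z-scores;
5. **cohort statistics** — compare the cohort discharged during a
   *focus week* (default March 23–29) of one year against the same
   calendar week of all other years: one-sided two-sample
   Kolmogorov–Smirnov tests on stay duration and age, and logistic
   regressions of same-calendar-year readmission;
6. **capsim** — a counterfactual in which every stay longer than *D*
   days is truncated to *D*, summarised as person-days of incarceration
   (the census integrated over the window) and its reduction fraction,
   broken down by status code.

Because the real portal snapshots are not archived, the package ships a
first-class **synthetic generator**: it simulates a ground-truth
population of per-person incarceration histories (calibrated to a mean
stay of 64 days, 9.0% female episodes, mean age at discharge ≈ 37, a
mean of about two episodes per person), projects it into the three
snapshot tables, and can inject a configurable count of every anomaly
class listed above while recording each injection in a ledger. Every
pipeline stage therefore has an exact round-trip oracle.

## The statistics at its core

* **One-sided two-sample KS test.** For samples A (size *n_a*) and B
  (size *n_b*) with ECDFs *F̂_A*, *F̂_B*, the statistic for the
  alternative "A is stochastically larger" is
  *D⁺ = sup_x [F̂_B(x) − F̂_A(x)]*, with asymptotic p-value
  *exp(−2mD⁺²)*, *m = n_a n_b/(n_a+n_b)*; an exact small-sample
  p-value is computed by lattice-path counting.
* **Readmission models.** With indicator *w* (discharge in the focus
  week), *y* (discharge in the focus year) and their interaction *wy*,
  model 1 is `logit P(readmit same calendar year) = β₀ + β₁w + β₂y +
  β₃wy`; model 2 adds the stay duration in days. Fits use
  iteratively reweighted least squares with step halving; standard
  errors come from the inverse observed information.
* **Cap counterfactual.** For cap *D*, episodes longer than *D* get
  discharge = admission + *D*; the person-days total over a window
  equals the daily census summed over it, and the reduction is
  1 − capped/uncapped.
* **Birth-date imputation.** Recorded integer ages at discharge imply,
  per record, a birth date `discharge − (age + 0.5) yr`; the imputed
  birth date is their arithmetic mean (the least-squares minimiser),
  ages are recomputed from it, and an individual whose ages move by
  more than five years is treated as having corrupt age data.

## Worked example

```python
from datetime import date
import jailstint as js

cfg = js.PipelineConfig(
    output_dir="demo", seed=7,
    synthetic=js.TruthConfig(
        n_individuals=5000,
        admission_window=(date(2013, 6, 1), date(2020, 12, 31)),
        coverage_start=date(2014, 1, 1),
        focus_week_effect=js.FocusWeekEffect(
            extra_discharges=40, readmission_odds_multiplier=0.5,
            age_shift_years=2.0)),
    corruption=js.CorruptionConfig(exact_duplicate_ads=10,
                                   status_conflict=25,
                                   same_day_inversion=15))
manifest = js.run_pipeline(cfg)
```

The run logs each stage the way the reports tally it:

```
synthetic truth: 9401 episodes, 5000 individuals
ingested 8971 ADS, 9204 DDS, 197 current rows
reconciliation removed 10 records ({'exact_duplicate': 10, ...})
merge accepted 9401 episodes: {1: 8764, 2: 0, 3: 440, 4: 0, 5: 0, 6: 197, 7: 0}
cleaning kept 9401 episodes
largest weekly decrease -33 in week of 2020-03-23
focus-week cohort 64 vs 132 prior; duration D=0.335 p=6.2e-05
```

Reading the numbers: the ten injected duplicate rows are the only
removals; the 440 category-3 episodes are admissions predating the
2014 coverage start (present only in the discharge file); the 197
category-6 episodes are still in custody on the data date. The planted
policy — 40 long-serving individuals released during March 23–29,
2020 — makes that week the largest weekly population drop (−33 net)
and makes the 2020 focus-week cohort's stay durations stochastically
larger than the 2014–2019 focus-week cohorts' (one-sided KS D = 0.335,
p ≈ 6·10⁻⁵). In the manifest, model 1's interaction estimate is
−1.26 (lower readmission odds specifically for focus-week-2020
discharges) and attenuates to −1.09 in model 2 once the stay duration
(−0.0018 per day) is controlled; capping stays at one year would have
removed 14.2% of person-days, at 100 days 50.3%.

The same stages are available from the shell:

```sh
jailstint run --config cfg.yaml
jailstint reconcile --ads ads.csv --dds dds.csv --out out/
jailstint capsim --episodes episodes.csv --window 2014-01-01:2020-12-31 \
    --data-date 2021-01-09 --out out/
```

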