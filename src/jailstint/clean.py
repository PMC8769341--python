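"""Cleaning the merged episode table.

Four passes, in order:

* demographics (race, gender) resolved per individual by the unique
  mode of all values pooled across that individual's episodes and
  source files, with ties and all-missing becoming missing;
* per-episode status code and top charge resolved across source files —
  a value beats a blank, a direct conflict becomes missing;
* age at discharge made self-consistent per individual by imputing the
  birth date that minimises the squared differences to the birth dates
  implied by each record (implied birth = discharge date − (age + 0.5)
  years, the midpoint of the integer-age interval), after first
  discarding physically impossible ages (117+); individuals for whom
  imputation moves any age by more than five years are treated as
  corrupt and lose all age data;
* the incarceration duration derived on calendar dates, with same-day
  and previous-day discharge/admission inversions repaired to a
  half-day stay, same-day stays counted as half a day, multi-year
  (>5 y) outliers excluded, and ongoing episodes measured to the data
  date.

Years are converted to days via 365.25 throughout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .synthetic_data import DAYS_PER_YEAR

AGE_CUTOFF = 117          # ages at or above this are treated as impossible
AGE_DISCREPANCY_YEARS = 5  # imputation shift that marks an individual corrupt
MAX_DURATION_DAYS = 5 * DAYS_PER_YEAR


@dataclass
class CleanReport:
    race_resolved_records: int = 0
    race_resolved_individuals: int = 0
    gender_resolved_records: int = 0
    gender_resolved_individuals: int = 0
    status_conflicts: int = 0
    charge_conflicts: int = 0
    age_case1_records: int = 0
    age_case1_individuals: int = 0
    age_case2_records: int = 0
    age_case2_individuals: int = 0
    age_case3_records: int = 0
    age_case3_individuals: int = 0
    age_117_plus: int = 0
    duration_case1_excluded: int = 0
    duration_case2_prevday_fixed: int = 0
    duration_case3_sameday_fixed: int = 0
    duration_case4_normal: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def resolve_categorical(values) -> object:
    """Unique mode of the non-missing values; tie or all-missing -> None."""
    present = [v for v in values if v is not None and not pd.isna(v)]
    if not present:
        return None
    counts = Counter(present).most_common()
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        return None
    return counts[0][0]


def resolve_demographics(episodes: pd.DataFrame,
                         report: CleanReport | None = None,
                         ) -> tuple[pd.DataFrame, CleanReport]:
    """Resolve race and gender per individual by pooled unique mode.

    Pools every value the individual carries across episodes and source
    files.  An episode counts as resolved when the final value differs
    from at least one of its own recorded values; an individual counts
    when any of their episodes does.
    """
    report = report or CleanReport()
    episodes = episodes.copy()
    for fld, rec_name, ind_name in (
            ("race", "race_resolved_records", "race_resolved_individuals"),
            ("gender", "gender_resolved_records",
             "gender_resolved_individuals")):
        a, b = episodes[f"{fld}_a"], episodes[f"{fld}_b"]
        pooled = pd.concat([
            episodes[["id"]].assign(value=a),
            episodes[["id"]].assign(value=b)])
        final = pooled.groupby("id")["value"].agg(resolve_categorical)
        episodes[fld] = episodes["id"].map(final)
        changed = ((a.notna() & (a != episodes[fld]))
                   | (b.notna() & (b != episodes[fld])))
        setattr(report, rec_name, int(changed.sum()))
        setattr(report, ind_name,
                int(episodes.loc[changed, "id"].nunique()))
    return episodes, report


def resolve_episode_fields(episodes: pd.DataFrame,
                           report: CleanReport | None = None,
                           ) -> tuple[pd.DataFrame, CleanReport]:
    """Resolve per-episode status code and top charge across sources.

    A present value beats a missing one; two different present values
    are a direct conflict and become missing.
    """
    report = report or CleanReport()
    episodes = episodes.copy()
    for fld, counter in (("status_code", "status_conflicts"),
                         ("top_charge", "charge_conflicts")):
        a, b = episodes[f"{fld}_a"], episodes[f"{fld}_b"]
        conflict = a.notna() & b.notna() & (a != b)
        episodes[fld] = a.where(a.notna(), b).where(~conflict, None)
        setattr(report, counter, int(conflict.sum()))
    return episodes, report


def impute_birthdates(episodes: pd.DataFrame,
                      report: CleanReport | None = None,
                      ) -> tuple[pd.DataFrame, CleanReport]:
    """Make ages self-consistent per individual via a least-squares birth date.

    The imputed birth date is the arithmetic mean of the per-record
    implied birth dates (the least-squares minimiser); ages are then
    recomputed from it.  Case 1: individuals whose records imply more
    than one birth date get recomputed ages.  Case 2: missing ages on
    discharged episodes are recovered from the imputed birth date.
    Case 3: if any recomputed age moves by more than five years the
    individual's age data is presumed corrupt and set to missing.
    Adds an ``imputed_birth_date`` column (per individual).
    """
    report = report or CleanReport()
    episodes = episodes.copy()

    age = pd.to_numeric(episodes["age_at_discharge"],
                        errors="coerce").astype(float)
    impossible = age >= AGE_CUTOFF
    report.age_117_plus = int(impossible.sum())
    age[impossible] = np.nan

    discharged = episodes["discharge_dt"].notna()
    ddate_days = (episodes["discharge_dt"].dt.normalize()
                  - pd.Timestamp("1970-01-01")).dt.days.astype(float)
    aged = discharged & age.notna()
    implied = ddate_days - (age + 0.5) * DAYS_PER_YEAR

    grp = episodes.loc[aged, "id"]
    birth_mean = implied[aged].groupby(grp).mean()
    n_aged = grp.groupby(grp).size()
    n_distinct = implied[aged].round(6).groupby(grp).nunique()

    b_hat = episodes["id"].map(birth_mean)
    recomputed = np.floor((ddate_days - b_hat) / DAYS_PER_YEAR)

    inconsistent_ids = n_distinct.index[(n_aged >= 2) & (n_distinct > 1)]
    shift = (recomputed - age).abs()
    corrupt_mask = aged & (shift > AGE_DISCREPANCY_YEARS)
    corrupt_ids = pd.Index(episodes.loc[corrupt_mask, "id"].unique())
    case1_ids = inconsistent_ids.difference(corrupt_ids)

    is_corrupt = episodes["id"].isin(corrupt_ids)
    is_case1 = episodes["id"].isin(case1_ids)
    has_birth = b_hat.notna() & ~is_corrupt
    recoverable = discharged & age.isna() & has_birth

    report.age_case3_records = int(is_corrupt.sum())
    report.age_case3_individuals = int(len(corrupt_ids))
    report.age_case1_records = int((aged & is_case1).sum())
    report.age_case1_individuals = int(len(case1_ids))
    report.age_case2_records = int(recoverable.sum())
    report.age_case2_individuals = int(
        episodes.loc[recoverable, "id"].nunique())

    new_age = age.copy()
    new_age[aged & is_case1] = recomputed[aged & is_case1]
    new_age[recoverable] = recomputed[recoverable]
    new_age[is_corrupt] = np.nan
    episodes["age_at_discharge"] = new_age.astype("Int64")
    episodes["imputed_birth_date"] = (
        pd.Timestamp("1970-01-01")
        + pd.to_timedelta(b_hat.where(~is_corrupt).round(), unit="D"))
    return episodes, report


def derive_duration(episodes: pd.DataFrame, data_date: date,
                    report: CleanReport | None = None,
                    ) -> tuple[pd.DataFrame, CleanReport]:
    """Derive the stay duration in days on calendar dates.

    Case 1: durations above five years are excluded as clerical errors.
    Case 2/3: previous-day and same-day inversions are repaired to a
    discharge at 23:59 on the admission day with a half-day duration.
    Case 4: duration = discharge date − admission date in whole days,
    with same-day stays counted as half a day.  Ongoing episodes use
    ``data_date`` in place of the discharge.

    Adds ``duration_days`` and ``effective_discharge_date`` (the
    date used for census membership) and drops excluded episodes.
    """
    report = report or CleanReport()
    episodes = episodes.copy()
    eff = episodes["discharge_dt"].fillna(pd.Timestamp(data_date))
    admit_date = episodes["admit_dt"].dt.normalize()
    eff_date = eff.dt.normalize()
    d = (eff_date - admit_date).dt.days

    if (d < -1).any():
        raise ValueError("gross date inversion survived reconciliation; "
                         "run reconcile() first")

    case1 = d > MAX_DURATION_DAYS
    case2 = d == -1
    case3 = (d == 0) & (eff < episodes["admit_dt"])
    report.duration_case1_excluded = int(case1.sum())
    report.duration_case2_prevday_fixed = int(case2.sum())
    report.duration_case3_sameday_fixed = int(case3.sum())
    report.duration_case4_normal = int((~(case1 | case2 | case3)).sum())

    repaired = (case2 | case3) & episodes["discharge_dt"].notna()
    episodes.loc[repaired, "discharge_dt"] = (
        admit_date[repaired] + pd.Timedelta(hours=23, minutes=59))

    duration = d.astype(float)
    duration[case2 | case3] = 0.5
    duration[(d == 0) & ~(case2 | case3)] = 0.5
    episodes["duration_days"] = duration
    episodes["effective_discharge_date"] = eff_date
    episodes.loc[case2 | case3, "effective_discharge_date"] = (
        admit_date[case2 | case3])

    episodes = episodes[~case1].reset_index(drop=True)
    episodes["duration_days"] = episodes["duration_days"].astype(float)
    return episodes, report


def clean_episodes(episodes: pd.DataFrame, data_date: date,
                   ) -> tuple[pd.DataFrame, CleanReport]:
    """Run the full cleaning sequence and return the final episode table."""
    report = CleanReport()
    episodes, report = resolve_demographics(episodes, report)
    episodes, report = resolve_episode_fields(episodes, report)
    episodes, report = impute_birthdates(episodes, report)
    episodes, report = derive_duration(episodes, data_date, report)
    return episodes, report
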