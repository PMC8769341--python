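"""Synthetic jail-record generator.

Produces a ground-truth table of incarceration episodes with known
person-level structure (demographics, birth dates, readmission dynamics,
a planted focus-week discharge policy), then projects it into the three
snapshot tables an open-data portal would publish — an admissions table
(ADS), a discharges table (DDS, which additionally carries integer age at
discharge), and a current-custody roster — optionally injecting a
configurable number of rows from each anomaly class the downstream
pipeline must handle.  Every injection is recorded in a ledger so each
pipeline stage has an exact bookkeeping oracle.

Units: durations and gaps are days; ages are years; date-times are kept
at minute resolution.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25

STATUS_CODES = ("CS", "CSP", "DE", "DEP", "DNS", "DPV", "SCO", "SSR")

#: column order of the canonical (internal) snapshot schema
ADS_COLUMNS = ["id", "admit_dt", "discharge_dt", "race", "gender",
               "status_code", "top_charge"]
DDS_COLUMNS = ADS_COLUMNS + ["age_at_discharge"]
CURRENT_COLUMNS = ["id", "admit_dt", "race", "gender", "status_code",
                   "top_charge"]

#: names of the anomaly classes the corruptor can inject
ANOMALY_CLASSES = (
    "exact_duplicate_ads",
    "conflicting_dds_pair",
    "cross_file_discharge_conflict",
    "gross_date_inversion",
    "missing_discharge_in_ads",
    "pre_window_admission",
    "dds_only_clerical",
    "ads_only_clerical",
    "current_only",
    "age_jitter_years",
    "age_outlier_117_plus",
    "age_missing",
    "demographic_flip",
    "status_conflict",
    "charge_conflict",
    "same_day_inversion",
    "previous_day_inversion",
    "multi_year_duration_outlier",
)

_CHARGE_CODES = ("140.20", "120.00", "160.15", "220.03", "125.25",
                 "105.10", "155.25", "VTL 511")
_RACES = ("Black", "Asian")


@dataclass(frozen=True)
class DurationLaw:
    """Mixture-of-exponentials stay-length law (days).

    The base mixture has a short, a medium and a long component; the
    component means are rescaled so that the mixture mean equals
    ``mean`` exactly.  Draws above ``cap_days`` are resampled so the
    truth never contains multi-year outliers unless they are injected
    deliberately.
    """

    mean: float = 64.0
    component_means: tuple[float, ...] = (2.0, 30.0, 250.0)
    weights: tuple[float, ...] = (0.35, 0.45, 0.20)
    cap_days: float = 1820.0

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("duration_law: mean must be positive")
        if len(self.component_means) != len(self.weights):
            raise ValueError("duration_law: means/weights length mismatch")
        if not np.isclose(sum(self.weights), 1.0):
            raise ValueError("duration_law: weights must sum to 1")

    @property
    def scaled_means(self) -> np.ndarray:
        base = np.asarray(self.component_means, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        return base * (self.mean / float(base @ w))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        means = self.scaled_means
        comp = rng.choice(len(means), size=n, p=np.asarray(self.weights))
        out = rng.exponential(means[comp])
        bad = out > self.cap_days
        while bad.any():
            out[bad] = rng.exponential(means[comp[bad]])
            bad = out > self.cap_days
        return out


def _truncated_exp_mean(mu: float, cap: float) -> float:
    """E[X | X < cap] for X ~ Exponential(mu)."""
    if mu <= 0:
        return 0.0
    r = cap / mu
    if r > 700:
        return mu
    return mu - cap / np.expm1(r)


@dataclass(frozen=True)
class AgeLaw:
    """Age at first admission, years: truncated normal.

    The default mean is set below the target mean age at discharge
    (37 y) because repeat admissions and stay lengths age the
    population between first admission and discharge.
    """

    mean: float = 35.3
    sd: float = 12.0
    minimum: float = 16.0
    maximum: float = 85.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        out = rng.normal(self.mean, self.sd, size=n)
        bad = (out < self.minimum) | (out > self.maximum)
        while bad.any():
            out[bad] = rng.normal(self.mean, self.sd, size=int(bad.sum()))
            bad = (out < self.minimum) | (out > self.maximum)
        return out


@dataclass(frozen=True)
class FocusWeekEffect:
    """Planted policy effect on episodes discharged during one week.

    ``week_start`` opens a 7-day window.  ``duration_multiplier``
    lengthens in-week discharges by back-dating their admission (the
    discharge date stays inside the week, emulating the release of
    long-serving individuals).  ``extra_discharges`` additionally picks
    that many episodes spanning the whole week and truncates their
    discharge into it, creating a net-population drop.
    ``readmission_odds_multiplier`` scales the odds of a further
    admission after an in-week discharge.  ``age_shift_years`` makes
    individuals with an in-week discharge older by shifting their birth
    date back.
    """

    week_start: date = date(2020, 3, 23)
    duration_multiplier: float = 1.0
    readmission_odds_multiplier: float = 1.0
    age_shift_years: float = 0.0
    extra_discharges: int = 0

    @property
    def week_end(self) -> date:
        """First day after the window (exclusive)."""
        return self.week_start + timedelta(days=7)


@dataclass(frozen=True)
class TruthConfig:
    n_individuals: int = 5000
    episodes_per_person_mean: float = 2.0
    duration_law: DurationLaw = field(default_factory=DurationLaw)
    female_fraction: float = 0.090
    age_law: AgeLaw = field(default_factory=AgeLaw)
    admission_window: tuple[date, date] = (date(2014, 1, 1), date(2020, 12, 31))
    coverage_start: date | None = None          # portal coverage; None = window start
    data_date: date | None = None               # scrape date; None = window end + 9d
    weekday_admission_weights: tuple[float, ...] = (
        1.15, 1.10, 1.10, 1.10, 1.10, 0.75, 0.70)   # Mon..Sun
    year_end_dip_depth: float = 0.0             # fractional admission thinning, late Dec
    focus_week_effect: FocusWeekEffect = field(default_factory=FocusWeekEffect)
    status_code_probabilities: dict[str, float] = field(default_factory=lambda: {
        "CS": 0.15, "CSP": 0.03, "DE": 0.56, "DEP": 0.06,
        "DNS": 0.04, "DPV": 0.05, "SCO": 0.02, "SSR": 0.09})
    status_missing_rate: float = 0.06
    charge_missing_rate: float = 0.677
    race_probabilities: dict[str, float] = field(default_factory=lambda: {
        "Black": 0.54, "Asian": 0.015})         # remainder missing
    # long stays concentrate in some statuses; rescaled to keep the overall mean
    status_duration_multipliers: dict[str, float] = field(
        default_factory=lambda: {"SSR": 6.0})
    readmission_gap_mean_days: float = 120.0
    duration_readmission_log_odds_per_day: float = -0.002
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if self.episodes_per_person_mean < 1:
            raise ValueError("episodes_per_person_mean must be >= 1")
        if not (0 <= self.female_fraction <= 1):
            raise ValueError("female_fraction must be in [0, 1]")
        if self.admission_window[0] >= self.admission_window[1]:
            raise ValueError("admission_window: start must precede end")
        w = np.asarray(self.weekday_admission_weights, dtype=float)
        if len(w) != 7 or (w < 0).any() or w.sum() == 0:
            raise ValueError("weekday_admission_weights must be 7 nonnegative "
                             "reals, not all zero")
        probs = self.status_code_probabilities
        if set(probs) != set(STATUS_CODES):
            raise ValueError("status_code_probabilities must cover exactly "
                             f"{STATUS_CODES}")
        if any(p < 0 for p in probs.values()) or not np.isclose(
                sum(probs.values()), 1.0):
            raise ValueError("status_code_probabilities must be a simplex")
        race_total = sum(self.race_probabilities.values())
        if any(p < 0 for p in self.race_probabilities.values()) or race_total > 1 + 1e-9:
            raise ValueError("race_probabilities must be nonnegative and sum to <= 1")
        for rate_name in ("status_missing_rate", "charge_missing_rate",
                          "year_end_dip_depth"):
            rate = getattr(self, rate_name)
            if not (0 <= rate <= 1):
                raise ValueError(f"{rate_name} must be in [0, 1]")

    @property
    def resolved_coverage_start(self) -> date:
        return self.coverage_start or self.admission_window[0]

    @property
    def resolved_data_date(self) -> date:
        return self.data_date or (self.admission_window[1] + timedelta(days=9))


@dataclass
class Truth:
    """Ground-truth output of :func:`generate_truth`."""

    episodes: pd.DataFrame
    persons: pd.DataFrame
    config: TruthConfig


def _sample_admission_days(config: TruthConfig, n: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Days since window start, weekday- (and optionally season-) weighted."""
    start, end = config.admission_window
    n_days = (end - start).days + 1
    days = pd.date_range(start, end, freq="D")
    weights = np.asarray(config.weekday_admission_weights, dtype=float)[
        days.weekday]
    if config.year_end_dip_depth > 0:
        dip = (days.month == 12) & (days.day >= 18)
        weights = weights * np.where(dip, 1.0 - config.year_end_dip_depth, 1.0)
    weights = weights / weights.sum()
    return rng.choice(n_days, size=n, p=weights)


def generate_truth(config: TruthConfig) -> Truth:
    """Simulate a ground-truth episode population.

    Each person receives a birth date, demographics, and a sequence of
    incarceration episodes: admission (weekday-weighted within the
    admission window), a stay length from the duration law (scaled per
    status code but renormalised so the overall mean equals the law's
    mean), and a Bernoulli continuation to the next admission whose
    log-odds depend on the stay length and, inside the focus week, on
    the planted readmission multiplier.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fx = config.focus_week_effect
    window_start, window_end = config.admission_window
    window_end_ts = pd.Timestamp(window_end) + pd.Timedelta(hours=23, minutes=59)
    week_start_ts = pd.Timestamp(fx.week_start)
    week_end_ts = pd.Timestamp(fx.week_end)

    n = config.n_individuals
    ids = np.arange(100_000, 100_000 + n)
    genders = np.where(rng.random(n) < config.female_fraction, "F", "M")
    race_names = list(config.race_probabilities)
    race_p = np.array([config.race_probabilities[r] for r in race_names])
    race_draw = rng.choice(len(race_names) + 1, size=n,
                           p=np.append(race_p, 1.0 - race_p.sum()))
    races = np.array(race_names + [None], dtype=object)[race_draw]

    first_admit_day = _sample_admission_days(config, n, rng)
    first_admit = (pd.Timestamp(window_start)
                   + pd.to_timedelta(first_admit_day, unit="D")
                   + pd.to_timedelta(rng.integers(0, 1440, size=n), unit="m"))
    age_at_first = config.age_law.sample(n, rng)
    birth = first_admit - pd.to_timedelta(age_at_first * DAYS_PER_YEAR, unit="D")
    birth = birth.normalize()

    # status-specific stay scaling.  Draws are exponentials truncated at the
    # law's cap, so a global scale factor is solved (bisection on the
    # closed-form truncated mean) to keep the overall mean exactly at the
    # law's mean despite the multipliers and the truncation.
    status_names = list(STATUS_CODES) + [None]
    status_p = np.array([config.status_code_probabilities[s] for s in STATUS_CODES])
    status_p = np.append(status_p * (1 - config.status_missing_rate),
                         config.status_missing_rate)
    mults = np.array([config.status_duration_multipliers.get(s, 1.0)
                      for s in STATUS_CODES] + [1.0])
    law = config.duration_law
    comp_means = law.scaled_means
    comp_w = np.asarray(law.weights)

    def _overall_mean(f: float) -> float:
        return float(sum(
            p * sum(w * _truncated_exp_mean(m * mult * f, law.cap_days)
                    for w, m in zip(comp_w, comp_means))
            for p, mult in zip(status_p, mults)))

    lo_f, hi_f = 1e-3, 1.0
    while _overall_mean(hi_f) < law.mean:
        hi_f *= 2.0
        if hi_f > 1e6:
            raise ValueError("duration_law mean unattainable under the cap")
    for _ in range(80):
        mid = 0.5 * (lo_f + hi_f)
        if _overall_mean(mid) < law.mean:
            lo_f = mid
        else:
            hi_f = mid
    dur_scale = 0.5 * (lo_f + hi_f)
    status_mu = np.outer(mults * dur_scale, comp_means)  # status x component

    base_cont = 1.0 - 1.0 / config.episodes_per_person_mean
    slope = config.duration_readmission_log_odds_per_day
    # centre the continuation probability at the configured mean despite the
    # duration-dependent term
    base_logit = (np.log(base_cont / (1 - base_cont)) if base_cont > 0
                  else -np.inf) - slope * config.duration_law.mean

    rows: list[tuple] = []
    fx_persons: set[int] = set()
    for i in range(n):
        admit = first_admit[i]
        while True:
            status_idx = rng.choice(len(status_names), p=status_p)
            status = status_names[status_idx]
            comp = rng.choice(len(comp_w), p=comp_w)
            mu = status_mu[status_idx, comp]
            duration = float(rng.exponential(mu))
            while duration > law.cap_days:
                duration = float(rng.exponential(mu))
            discharge = admit + pd.Timedelta(days=duration)
            in_week = week_start_ts <= discharge < week_end_ts
            if in_week and fx.duration_multiplier != 1.0:
                # lengthen the stay while keeping the discharge in the week
                duration = min(duration * fx.duration_multiplier,
                               config.duration_law.cap_days)
                admit = discharge - pd.Timedelta(days=duration)
            if in_week:
                fx_persons.add(i)
            charge = (None if rng.random() < config.charge_missing_rate
                      else _CHARGE_CODES[rng.integers(0, len(_CHARGE_CODES))])
            rows.append((ids[i], admit.floor("min"), discharge.floor("min"),
                         status, charge))
            logit = base_logit + slope * duration
            if in_week:
                logit += np.log(fx.readmission_odds_multiplier)
            p_cont = 1.0 / (1.0 + np.exp(-logit))
            if rng.random() >= p_cont:
                break
            gap = max(rng.exponential(config.readmission_gap_mean_days), 0.25)
            admit = discharge + pd.Timedelta(days=gap)
            if admit > window_end_ts:
                break
            admit = admit.floor("min")

    episodes = pd.DataFrame(rows, columns=["id", "admit_dt", "discharge_dt",
                                           "status_code", "top_charge"])

    if fx.extra_discharges > 0:
        spanning = episodes.index[
            (episodes["admit_dt"] < week_start_ts)
            & (episodes["discharge_dt"] >= week_end_ts)]
        if len(spanning) < fx.extra_discharges:
            raise ValueError(
                "focus_week_effect.extra_discharges exceeds the number of "
                f"episodes spanning the week ({len(spanning)} available)")
        chosen = rng.choice(spanning.to_numpy(), size=fx.extra_discharges,
                            replace=False)
        new_discharge = (week_start_ts
                         + pd.to_timedelta(rng.integers(0, 7 * 1440,
                                                        size=len(chosen)),
                                           unit="m"))
        episodes.loc[chosen, "discharge_dt"] = new_discharge
        person_pos = episodes.loc[chosen, "id"].to_numpy() - 100_000
        fx_persons.update(person_pos.tolist())

    if fx.age_shift_years != 0.0 and fx_persons:
        idx = np.array(sorted(fx_persons))
        birth_vals = birth.to_numpy().copy()
        birth_vals[idx] = (pd.DatetimeIndex(birth_vals[idx])
                           - pd.Timedelta(days=fx.age_shift_years
                                          * DAYS_PER_YEAR)).normalize().to_numpy()
        birth = pd.DatetimeIndex(birth_vals)

    persons = pd.DataFrame({"id": ids, "birth_date": birth,
                            "race": races, "gender": genders})
    episodes = episodes.merge(persons, on="id", how="left")
    episodes = episodes[["id", "admit_dt", "discharge_dt", "race", "gender",
                         "status_code", "top_charge", "birth_date"]]
    dup = episodes.duplicated(subset=["id", "admit_dt"])
    if dup.any():
        raise RuntimeError("internal error: duplicate (id, admit_dt) in truth")
    return Truth(episodes=episodes, persons=persons, config=config)


# ---------------------------------------------------------------------------
# corruption


def _zero_counts() -> dict[str, int]:
    return {name: 0 for name in ANOMALY_CLASSES}


@dataclass(frozen=True)
class CorruptionConfig:
    """Requested injection count per anomaly class (all default 0)."""

    exact_duplicate_ads: int = 0
    conflicting_dds_pair: int = 0
    cross_file_discharge_conflict: int = 0
    gross_date_inversion: int = 0
    missing_discharge_in_ads: int = 0
    pre_window_admission: int = 0
    dds_only_clerical: int = 0
    ads_only_clerical: int = 0
    current_only: int = 0
    age_jitter_years: int = 0
    age_outlier_117_plus: int = 0
    age_missing: int = 0
    demographic_flip: int = 0
    status_conflict: int = 0
    charge_conflict: int = 0
    same_day_inversion: int = 0
    previous_day_inversion: int = 0
    multi_year_duration_outlier: int = 0
    age_jitter_magnitude_years: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        for name in ANOMALY_CLASSES:
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer")
        if self.age_jitter_magnitude_years < 0:
            raise ValueError("age_jitter_magnitude_years must be nonnegative")

    def counts(self) -> dict[str, int]:
        return {name: int(getattr(self, name)) for name in ANOMALY_CLASSES}


@dataclass
class CorruptionLedger:
    """Record of every injected anomaly.

    ``entries`` has one row per injected/affected snapshot row with the
    anomaly class, the truth episode it came from, the snapshot it lives
    in, its final row position there, and (where relevant) the field
    touched.  ``counts`` holds the requested injection count per class.
    """

    entries: pd.DataFrame
    counts: dict[str, int] = field(default_factory=_zero_counts)

    def refs(self, anomaly_class: str) -> pd.DataFrame:
        return self.entries[self.entries["anomaly_class"] == anomaly_class]

    @staticmethod
    def empty() -> "CorruptionLedger":
        entries = pd.DataFrame(columns=["anomaly_class", "truth_index",
                                        "snapshot", "row", "field"])
        return CorruptionLedger(entries=entries)


def base_snapshots(truth: Truth) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Project truth into uncorrupted ADS / DDS / current tables.

    ADS lists admissions on or after the portal coverage start, with the
    discharge blank for episodes still in custody on the data date.  DDS
    lists completed episodes (any admission date) and adds integer age
    at discharge.  The current roster lists episodes in custody on the
    data date.  Each output carries a ``truth_index`` column pointing at
    the truth episode (dropped when written to CSV).
    """
    config = truth.config
    coverage_ts = pd.Timestamp(config.resolved_coverage_start)
    data_ts = (pd.Timestamp(config.resolved_data_date)
               + pd.Timedelta(hours=23, minutes=59))
    ep = truth.episodes.reset_index().rename(columns={"index": "truth_index"})
    discharged = ep["discharge_dt"] <= data_ts
    in_coverage = ep["admit_dt"] >= coverage_ts

    ads = ep[in_coverage].copy()
    ads.loc[~discharged[in_coverage], "discharge_dt"] = pd.NaT
    ads = ads[["truth_index"] + ADS_COLUMNS].reset_index(drop=True)

    dds = ep[discharged].copy()
    age_years = ((dds["discharge_dt"].dt.normalize()
                  - dds["birth_date"]).dt.days / DAYS_PER_YEAR)
    dds["age_at_discharge"] = np.floor(age_years).astype("Int64")
    dds = dds[["truth_index"] + DDS_COLUMNS].reset_index(drop=True)

    current = ep[~discharged].copy()
    current = current[["truth_index"] + CURRENT_COLUMNS].reset_index(drop=True)
    return ads, dds, current


class _Sampler:
    """Samples injection targets on disjoint individuals.

    Every class draws truth episodes whose person has not been touched
    by any other injection, so the downstream effect of each anomaly is
    independent and exactly predictable from the ledger.
    """

    def __init__(self, rng: np.random.Generator, person_of: pd.Series):
        self.rng = rng
        self.person_of = person_of
        self.used_persons: set = set()

    def take(self, pool: np.ndarray, k: int, class_name: str) -> np.ndarray:
        order = self.rng.permutation(np.asarray(pool))
        chosen: list[int] = []
        for tix in order:
            pid = self.person_of[int(tix)]
            if pid in self.used_persons:
                continue
            self.used_persons.add(pid)
            chosen.append(int(tix))
            if len(chosen) == k:
                break
        if len(chosen) < k:
            raise ValueError(
                f"corruption class {class_name}: requested {k} rows but only "
                f"{len(chosen)} eligible individuals remain")
        return np.array(chosen)


def corrupt_to_snapshots(
    truth: Truth,
    corruption: CorruptionConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, CorruptionLedger]:
    """Emit ADS/DDS/current snapshots with injected anomalies.

    Injection classes target disjoint truth episodes, so the ledger maps
    each downstream report count to an exact expectation.  With an
    all-zero config the outputs equal :func:`base_snapshots` and the
    ledger is empty.
    """
    corruption.validate()
    rng = np.random.default_rng(corruption.seed)
    config = truth.config
    coverage_ts = pd.Timestamp(config.resolved_coverage_start)
    ads, dds, current = base_snapshots(truth)
    sampler = _Sampler(rng, truth.episodes["id"])
    ledger_rows: list[dict] = []

    # lookup: truth_index -> row position per snapshot
    ads_pos = pd.Series(ads.index, index=ads["truth_index"])
    dds_pos = pd.Series(dds.index, index=dds["truth_index"])
    cur_pos = pd.Series(current.index, index=current["truth_index"])

    matched = np.intersect1d(ads.loc[ads["discharge_dt"].notna(),
                                     "truth_index"].to_numpy(),
                             dds["truth_index"].to_numpy())
    ongoing = np.intersect1d(ads.loc[ads["discharge_dt"].isna(),
                                     "truth_index"].to_numpy(),
                             current["truth_index"].to_numpy())
    dds_all = dds["truth_index"].to_numpy()

    ads_drop: list[int] = []
    dds_drop: list[int] = []
    ads_append: list[pd.DataFrame] = []
    dds_append: list[pd.DataFrame] = []

    def log(cls: str, tix, snapshot: str, row, field_name=None) -> None:
        ledger_rows.append({"anomaly_class": cls, "truth_index": int(tix),
                            "snapshot": snapshot, "row": row,
                            "field": field_name})

    # --- classes that only add rows -------------------------------------
    ads_append_ledger: list[int] = []   # ledger_rows index of each appended ADS row
    dds_append_ledger: list[int] = []

    k = corruption.exact_duplicate_ads
    if k:
        pool = ads["truth_index"].to_numpy()
        for tix in sampler.take(pool, k, "exact_duplicate_ads"):
            src = ads_pos[tix]
            ads_append.append(ads.loc[[src]])
            log("exact_duplicate_ads", tix, "ADS", None)
            ads_append_ledger.append(len(ledger_rows) - 1)

    k = corruption.conflicting_dds_pair
    if k:
        for tix in sampler.take(matched, k, "conflicting_dds_pair"):
            src = dds_pos[tix]
            twin = dds.loc[[src]].copy()
            twin["discharge_dt"] = (twin["discharge_dt"]
                                    + pd.Timedelta(days=int(rng.integers(1, 30))))
            dds_append.append(twin)
            log("conflicting_dds_pair", tix, "DDS", int(src))
            log("conflicting_dds_pair", tix, "DDS", None)  # appended twin
            dds_append_ledger.append(len(ledger_rows) - 1)

    # --- classes that modify matched rows in place ----------------------
    k = corruption.cross_file_discharge_conflict
    if k:
        for tix in sampler.take(matched, k, "cross_file_discharge_conflict"):
            row = dds_pos[tix]
            dds.loc[row, "discharge_dt"] = (
                dds.loc[row, "discharge_dt"]
                + pd.Timedelta(days=int(rng.integers(1, 30))))
            log("cross_file_discharge_conflict", tix, "DDS", int(row),
                "discharge_dt")

    k = corruption.gross_date_inversion
    if k:
        # same inverted discharge written to both files, so both rows are
        # removed at reconciliation and the episode vanishes
        for tix in sampler.take(matched, k, "gross_date_inversion"):
            arow, drow = ads_pos[tix], dds_pos[tix]
            bad = (ads.loc[arow, "admit_dt"]
                   - pd.Timedelta(days=int(rng.integers(2, 60))))
            ads.loc[arow, "discharge_dt"] = bad
            dds.loc[drow, "discharge_dt"] = bad
            log("gross_date_inversion", tix, "ADS", int(arow), "discharge_dt")
            log("gross_date_inversion", tix, "DDS", int(drow), "discharge_dt")

    k = corruption.missing_discharge_in_ads
    if k:
        for tix in sampler.take(matched, k, "missing_discharge_in_ads"):
            row = ads_pos[tix]
            ads.loc[row, "discharge_dt"] = pd.NaT
            log("missing_discharge_in_ads", tix, "ADS", int(row),
                "discharge_dt")

    k = corruption.pre_window_admission
    if k:
        # shift the whole episode so it straddles the coverage start: the
        # stay length is preserved and the recorded age follows the new
        # discharge, so only the admission's position is anomalous
        ep = truth.episodes
        dur_days = (ep["discharge_dt"] - ep["admit_dt"]).dt.days
        pool = np.asarray([t for t in matched if dur_days[t] >= 11])
        for tix in sampler.take(pool, k, "pre_window_admission"):
            drow = dds_pos[tix]
            back = int(min(rng.integers(10, 300), dur_days[tix] - 1))
            new_admit = (coverage_ts - pd.Timedelta(
                days=back, minutes=int(rng.integers(0, 1440)))).floor("min")
            new_discharge = new_admit + (ep.loc[tix, "discharge_dt"]
                                         - ep.loc[tix, "admit_dt"])
            dds.loc[drow, "admit_dt"] = new_admit
            dds.loc[drow, "discharge_dt"] = new_discharge.floor("min")
            dds.loc[drow, "age_at_discharge"] = int(np.floor(
                (new_discharge.normalize() - ep.loc[tix, "birth_date"]).days
                / DAYS_PER_YEAR))
            ads_drop.append(int(ads_pos[tix]))
            log("pre_window_admission", tix, "DDS", int(drow), "admit_dt")

    k = corruption.dds_only_clerical
    if k:
        for tix in sampler.take(matched, k, "dds_only_clerical"):
            ads_drop.append(int(ads_pos[tix]))
            log("dds_only_clerical", tix, "DDS", int(dds_pos[tix]))

    k = corruption.ads_only_clerical
    if k:
        for tix in sampler.take(matched, k, "ads_only_clerical"):
            dds_drop.append(int(dds_pos[tix]))
            log("ads_only_clerical", tix, "ADS", int(ads_pos[tix]))

    k = corruption.current_only
    if k:
        for tix in sampler.take(ongoing, k, "current_only"):
            ads_drop.append(int(ads_pos[tix]))
            log("current_only", tix, "CURRENT", int(cur_pos[tix]))

    # --- age classes (DDS only) -----------------------------------------
    k = corruption.age_jitter_years
    if k:
        mag = corruption.age_jitter_magnitude_years
        for tix in sampler.take(dds_all, k, "age_jitter_years"):
            row = dds_pos[tix]
            old = int(dds.loc[row, "age_at_discharge"])
            # keep the full magnitude: jitter downward only when it stays
            # in a plausible age range
            sign = -1 if (rng.random() < 0.5 and old - round(mag) >= 16) else 1
            dds.loc[row, "age_at_discharge"] = old + sign * round(mag)
            log("age_jitter_years", tix, "DDS", int(row), "age_at_discharge")

    k = corruption.age_outlier_117_plus
    if k:
        for tix in sampler.take(dds_all, k, "age_outlier_117_plus"):
            row = dds_pos[tix]
            dds.loc[row, "age_at_discharge"] = int(117 + rng.integers(0, 800))
            log("age_outlier_117_plus", tix, "DDS", int(row),
                "age_at_discharge")

    k = corruption.age_missing
    if k:
        for tix in sampler.take(dds_all, k, "age_missing"):
            row = dds_pos[tix]
            dds.loc[row, "age_at_discharge"] = pd.NA
            log("age_missing", tix, "DDS", int(row), "age_at_discharge")

    # --- demographic / per-episode field conflicts ----------------------
    k = corruption.demographic_flip
    if k:
        # one flip per distinct person, in the DDS copy; race flips only
        # target persons with a recorded race so every flip is a real
        # disagreement the mode-resolution stage can detect
        person_of = dds.set_index("truth_index")["id"]
        race_of = dds.set_index("truth_index")["race"]
        pool_persons = pd.Series(matched).map(person_of)
        keep = ~pool_persons.duplicated()
        pool = np.asarray(matched)[keep.to_numpy()]
        for tix in sampler.take(pool, k, "demographic_flip"):
            row = dds_pos[tix]
            flip_race = rng.random() < 0.5 and pd.notna(race_of[tix])
            if flip_race:
                old = dds.loc[row, "race"]
                new = "Asian" if old == "Black" else "Black"
                dds.loc[row, "race"] = new
                log("demographic_flip", tix, "DDS", int(row), "race")
            else:
                old = dds.loc[row, "gender"]
                dds.loc[row, "gender"] = "F" if old == "M" else "M"
                log("demographic_flip", tix, "DDS", int(row), "gender")

    k = corruption.status_conflict
    if k:
        has_status = dds.set_index("truth_index")["status_code"].notna()
        pool = np.asarray([t for t in matched if has_status.get(t, False)])
        for tix in sampler.take(pool, k, "status_conflict"):
            row = dds_pos[tix]
            old = dds.loc[row, "status_code"]
            others = [s for s in STATUS_CODES if s != old]
            dds.loc[row, "status_code"] = others[rng.integers(0, len(others))]
            log("status_conflict", tix, "DDS", int(row), "status_code")

    k = corruption.charge_conflict
    if k:
        has_charge = dds.set_index("truth_index")["top_charge"].notna()
        pool = np.asarray([t for t in matched if has_charge.get(t, False)])
        for tix in sampler.take(pool, k, "charge_conflict"):
            row = dds_pos[tix]
            old = dds.loc[row, "top_charge"]
            others = [c for c in _CHARGE_CODES if c != old]
            dds.loc[row, "top_charge"] = others[rng.integers(0, len(others))]
            log("charge_conflict", tix, "DDS", int(row), "top_charge")

    # --- date inversions repaired downstream ----------------------------
    def _set_both_discharges(tix, value) -> tuple[int, int]:
        arow, drow = ads_pos[tix], dds_pos[tix]
        ads.loc[arow, "discharge_dt"] = value
        dds.loc[drow, "discharge_dt"] = value
        return int(arow), int(drow)

    k = corruption.same_day_inversion
    if k:
        admit_min = (ads.set_index("truth_index")["admit_dt"].dt.hour * 60
                     + ads.set_index("truth_index")["admit_dt"].dt.minute)
        pool = np.asarray([t for t in matched if admit_min.get(t, 0) >= 30])
        for tix in sampler.take(pool, k, "same_day_inversion"):
            admit = ads.loc[ads_pos[tix], "admit_dt"]
            bad = admit - pd.Timedelta(minutes=int(rng.integers(5, 25)))
            arow, drow = _set_both_discharges(tix, bad)
            log("same_day_inversion", tix, "ADS", arow, "discharge_dt")
            log("same_day_inversion", tix, "DDS", drow, "discharge_dt")

    k = corruption.previous_day_inversion
    if k:
        for tix in sampler.take(matched, k, "previous_day_inversion"):
            admit = ads.loc[ads_pos[tix], "admit_dt"]
            bad = (admit.normalize() - pd.Timedelta(days=1)
                   + pd.Timedelta(hours=int(rng.integers(8, 23))))
            arow, drow = _set_both_discharges(tix, bad)
            log("previous_day_inversion", tix, "ADS", arow, "discharge_dt")
            log("previous_day_inversion", tix, "DDS", drow, "discharge_dt")

    k = corruption.multi_year_duration_outlier
    if k:
        birth_of = truth.episodes["birth_date"]
        for tix in sampler.take(matched, k, "multi_year_duration_outlier"):
            admit = ads.loc[ads_pos[tix], "admit_dt"]
            bad = admit + pd.Timedelta(days=int(5 * DAYS_PER_YEAR)
                                       + int(rng.integers(30, 1000)))
            arow, drow = _set_both_discharges(tix, bad)
            # the recorded age follows the (bogus) discharge date, so the
            # anomaly is purely a date error, not also an age error
            new_age = int(np.floor((bad.normalize() - birth_of[tix]).days
                                   / DAYS_PER_YEAR))
            dds.loc[drow, "age_at_discharge"] = new_age
            log("multi_year_duration_outlier", tix, "ADS", arow,
                "discharge_dt")
            log("multi_year_duration_outlier", tix, "DDS", drow,
                "discharge_dt")

    # --- apply appends and deletions, then renumber ledger refs ---------
    ads["_orig"] = ads.index
    dds["_orig"] = dds.index
    # appended rows get sentinel keys so the ledger can find their final slot
    if ads_append:
        extra = pd.concat(ads_append, ignore_index=True)
        extra["_orig"] = [-(i + 2) for i in range(len(extra))]
        ads = pd.concat([ads, extra], ignore_index=True)
    if dds_append:
        extra = pd.concat(dds_append, ignore_index=True)
        extra["_orig"] = [-(i + 2) for i in range(len(extra))]
        dds = pd.concat([dds, extra], ignore_index=True)
    ads = ads[~ads["_orig"].isin(ads_drop)].reset_index(drop=True)
    dds = dds[~dds["_orig"].isin(dds_drop)].reset_index(drop=True)

    ads_map = {int(o): i for i, o in enumerate(ads["_orig"])}
    dds_map = {int(o): i for i, o in enumerate(dds["_orig"])}
    for entry in ledger_rows:
        if entry["row"] is None:
            continue
        if entry["snapshot"] == "ADS":
            entry["row"] = ads_map.get(entry["row"])
        elif entry["snapshot"] == "DDS":
            entry["row"] = dds_map.get(entry["row"])
    for j, lix in enumerate(ads_append_ledger):
        ledger_rows[lix]["row"] = ads_map[-(j + 2)]
    for j, lix in enumerate(dds_append_ledger):
        ledger_rows[lix]["row"] = dds_map[-(j + 2)]
    ads = ads.drop(columns="_orig")
    dds = dds.drop(columns="_orig")

    entries = pd.DataFrame(ledger_rows, columns=["anomaly_class", "truth_index",
                                                 "snapshot", "row", "field"])
    ledger = CorruptionLedger(entries=entries, counts=corruption.counts())
    return ads, dds, current, ledger


# ---------------------------------------------------------------------------
# CSV emission

PORTAL_COLUMN_MAP = {
    "id": "INMATEID",
    "admit_dt": "ADMITTED_DT",
    "discharge_dt": "DISCHARGED_DT",
    "race": "RACE",
    "gender": "GENDER",
    "status_code": "INMATE_STATUS_CODE",
    "top_charge": "TOP_CHARGE",
    "age_at_discharge": "AGE",
}


def write_snapshots(ads: pd.DataFrame, dds: pd.DataFrame,
                    current: pd.DataFrame, outdir, *,
                    column_map: dict[str, str] | None = None,
                    ledger: CorruptionLedger | None = None) -> dict[str, str]:
    """Write the three snapshots (and optionally the ledger) as CSVs.

    Date-times are emitted as ISO-8601 to minute resolution; internal
    bookkeeping columns are dropped.  Returns the paths written.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    column_map = column_map or PORTAL_COLUMN_MAP
    paths = {}
    for name, frame, cols in (("ads", ads, ADS_COLUMNS),
                              ("dds", dds, DDS_COLUMNS),
                              ("current", current, CURRENT_COLUMNS)):
        out = frame[cols].copy()
        for col in ("admit_dt", "discharge_dt"):
            if col in out:
                out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M")
        out = out.rename(columns=column_map)
        path = outdir / f"{name}.csv"
        out.to_csv(path, index=False)
        paths[name] = str(path)
    if ledger is not None:
        path = outdir / "corruption_ledger.csv"
        ledger.entries.to_csv(path, index=False)
        paths["ledger"] = str(path)
    return paths
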