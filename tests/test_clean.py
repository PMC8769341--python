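"""Demographic resolution, birth-date imputation, duration derivation."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import jailstint as js
from conftest import run_chain


# ---------------------------------------------------------------------------
# resolve_categorical

@pytest.mark.parametrize("values,expected", [
    (["Black", "Black", "Asian"], "Black"),
    (["Black", "Asian"], None),                 # tie -> missing
    ([None, None], None),
    ([None, "Asian", None], "Asian"),
    ([], None),
    (["M", "M", "F", "F", "F"], "F"),
])
def test_resolve_categorical_examples(values, expected):
    assert js.resolve_categorical(values) == expected


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.lists(st.sampled_from(["A", "B", "C", None]), max_size=12),
       st.randoms(use_true_random=False))
def test_resolve_categorical_permutation_invariant_and_idempotent(vals, rnd):
    out = js.resolve_categorical(vals)
    shuffled = list(vals)
    rnd.shuffle(shuffled)
    assert js.resolve_categorical(shuffled) == out
    # resolving the resolved value again is a fixed point
    assert js.resolve_categorical([out] if out is not None else []) == out


# ---------------------------------------------------------------------------
# per-person / per-episode resolution

def _episodes(rows):
    cols = ["id", "admit_dt", "discharge_dt", "race_a", "race_b",
            "gender_a", "gender_b", "status_code_a", "status_code_b",
            "top_charge_a", "top_charge_b", "age_at_discharge"]
    df = pd.DataFrame(rows, columns=cols)
    for c in ("admit_dt", "discharge_dt"):
        df[c] = pd.to_datetime(df[c])
    df["age_at_discharge"] = df["age_at_discharge"].astype("Int64")
    return df


def test_resolve_demographics_mode_and_tie():
    eps = _episodes([
        ["p1", "2015-01-01", "2015-02-01", "Black", "Black", "M", "M",
         None, None, None, None, 30],
        ["p1", "2016-01-01", "2016-02-01", None, "Black", "M", "M",
         None, None, None, None, 31],
        ["p1", "2017-01-01", "2017-02-01", "Black", "Asian", "M", "M",
         None, None, None, None, 32],
        ["p2", "2015-01-01", "2015-02-01", None, None, "M", "F",
         None, None, None, None, 40],
    ])
    out, rep = js.resolve_demographics(eps)
    assert (out.loc[out["id"] == "p1", "race"] == "Black").all()
    assert rep.race_resolved_records == 1          # only the conflicted row
    assert rep.race_resolved_individuals == 1
    # p2 gender tie -> missing for the individual
    assert out.loc[out["id"] == "p2", "gender"].isna().all()
    assert rep.gender_resolved_individuals == 1


def test_resolve_episode_fields_rules():
    eps = _episodes([
        ["p1", "2015-01-01", "2015-02-01", None, None, None, None,
         "DE", None, "140.20", "140.20", 30],
        ["p1", "2016-01-01", "2016-02-01", None, None, None, None,
         "DE", "CS", None, "120.00", 31],
    ])
    out, rep = js.resolve_episode_fields(eps)
    assert out.loc[0, "status_code"] == "DE"       # value beats blank
    assert pd.isna(out.loc[1, "status_code"])      # conflict -> missing
    assert out.loc[1, "top_charge"] == "120.00"
    assert rep.status_conflicts == 1
    assert rep.charge_conflicts == 0


def test_demographic_flips_detected(small_truth):
    corr = js.CorruptionConfig(demographic_flip=25, seed=31)
    art = run_chain(small_truth, corr)
    flips = art["ledger"].refs("demographic_flip")
    rep = art["clean_report"]
    n_race = int((flips["field"] == "race").sum())
    n_gender = int((flips["field"] == "gender").sum())
    assert n_race + n_gender == 25
    assert rep.race_resolved_records == n_race
    assert rep.gender_resolved_records == n_gender
    assert rep.race_resolved_individuals == n_race
    assert rep.gender_resolved_individuals == n_gender


# ---------------------------------------------------------------------------
# birth-date imputation

def _aged(rows):
    """rows: (id, discharge ISO date, age or None)"""
    return _episodes([
        [pid, d, d, None, None, "M", None, None, None, None, None, age]
        for pid, d, age in rows])


def test_implied_birthdate_mean():
    """Two implied birth dates two days apart impute to their midpoint."""
    # ages chosen so implied births are exactly 2 days apart
    eps = _aged([("p", "2020-01-01", 20), ("p", "2020-01-03", 20)])
    out, rep = js.impute_birthdates(eps)
    b = out["imputed_birth_date"].iloc[0]
    implied0 = (pd.Timestamp("2020-01-01")
                - pd.Timedelta(days=20.5 * 365.25))
    assert abs((b - implied0).days - 1) <= 1


def test_age_117_set_missing():
    eps = _aged([("p", "2020-01-01", 117), ("q", "2020-01-01", 130)])
    out, rep = js.impute_birthdates(eps)
    assert rep.age_117_plus == 2
    assert out["age_at_discharge"].isna().all()


def test_large_discrepancy_poisons_individual():
    eps = _aged([("p", "2014-01-01", 30), ("p", "2020-01-01", 48),
                 ("q", "2014-01-01", 30), ("q", "2020-01-01", 36)])
    out, rep = js.impute_birthdates(eps)
    # p's records imply birth dates 12 years apart -> all ages removed
    assert out.loc[out["id"] == "p", "age_at_discharge"].isna().all()
    assert rep.age_case3_individuals == 1
    assert rep.age_case3_records == 2
    # q is merely inconsistent: ages recomputed, not removed
    assert out.loc[out["id"] == "q", "age_at_discharge"].notna().all()
    assert rep.age_case1_individuals == 1


def test_missing_age_recovered_from_other_records():
    eps = _aged([("p", "2020-01-01", 40), ("p", "2020-06-01", None)])
    out, rep = js.impute_birthdates(eps)
    assert rep.age_case2_records == 1
    assert int(out.loc[1, "age_at_discharge"]) in (40, 41)


def test_self_consistent_ages_recovered_exactly():
    """Records implying one common birth date keep their recorded ages."""
    base = pd.Timestamp("2015-03-10")
    rows = []
    for k in range(4):
        d = base + pd.Timedelta(days=round(k * 365.25))
        rows.append(("p", d.strftime("%Y-%m-%d"), 25 + k))
    eps = _aged(rows)
    out, rep = js.impute_birthdates(eps)
    assert list(out["age_at_discharge"]) == [25, 26, 27, 28]


def test_imputed_ages_close_to_recorded_on_synthetic(clean_baseline,
                                                     small_truth):
    """Integer-truncated ages move by less than a year on average."""
    cleaned = clean_baseline["cleaned"]
    dds = clean_baseline["dds"]
    recorded = dds.set_index(["id", "admit_dt"])["age_at_discharge"]
    cleaned = cleaned[cleaned["discharge_dt"].notna()]
    key = pd.MultiIndex.from_frame(
        cleaned[["id", "admit_dt"]].assign(id=cleaned["id"].astype(int)))
    rec = recorded.reindex(key).to_numpy(dtype=float)
    imp = cleaned["age_at_discharge"].to_numpy(dtype=float)
    ok = ~np.isnan(rec) & ~np.isnan(imp)
    assert ok.sum() > 1000
    assert np.abs(imp[ok] - rec[ok]).mean() < 1.0


# ---------------------------------------------------------------------------
# duration derivation

def _dur_eps(rows):
    """rows: (id, admit, discharge-or-None)"""
    return _episodes([
        [pid, a, d, None, None, "M", None, None, None, None, None, None]
        for pid, a, d in rows])


def test_duration_cases():
    eps = _dur_eps([
        ("a", "2014-01-10 09:00", "2014-01-20 12:00"),    # 10 days
        ("b", "2015-03-04 10:00", "2015-03-03 08:00"),    # prev-day inversion
        ("c", "2016-07-07 09:00", "2016-07-07 18:00"),    # same day
        ("d", "2016-07-07 09:00", "2016-07-07 08:00"),    # same-day inversion
        ("e", "2013-01-01 00:00", "2019-06-01 00:00"),    # > 5 years
        ("f", "2020-06-01 00:00", None),                  # ongoing
    ])
    out, rep = js.derive_duration(eps, date(2021, 1, 9))
    by_id = out.set_index("id")
    assert by_id.loc["a", "duration_days"] == 10.0
    assert by_id.loc["b", "duration_days"] == 0.5
    assert by_id.loc["b", "discharge_dt"] == pd.Timestamp("2015-03-04 23:59")
    assert by_id.loc["c", "duration_days"] == 0.5
    assert by_id.loc["d", "duration_days"] == 0.5
    assert "e" not in by_id.index
    assert by_id.loc["f", "duration_days"] == float(
        (date(2021, 1, 9) - date(2020, 6, 1)).days)
    assert rep.duration_case1_excluded == 1
    assert rep.duration_case2_prevday_fixed == 1
    assert rep.duration_case3_sameday_fixed == 1
    assert rep.duration_case4_normal == 3


def test_duration_bounds_after_cleaning(clean_baseline):
    d = clean_baseline["cleaned"]["duration_days"]
    assert (d >= 0.5).all() and (d <= 5 * 365.25).all()


def test_duration_case_counts_match_ledger(small_truth):
    corr = js.CorruptionConfig(
        same_day_inversion=14, previous_day_inversion=15,
        multi_year_duration_outlier=16, age_outlier_117_plus=17, seed=37)
    art = run_chain(small_truth, corr)
    rep = art["clean_report"]
    assert rep.duration_case3_sameday_fixed == 14
    assert rep.duration_case2_prevday_fixed == 15
    assert rep.duration_case1_excluded == 16
    assert rep.age_117_plus == 17


def test_gross_inversion_must_be_reconciled_first():
    eps = _dur_eps([("a", "2017-06-01 10:00", "2017-05-01 10:00")])
    with pytest.raises(ValueError, match="reconcil"):
        js.derive_duration(eps, date(2021, 1, 9))
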