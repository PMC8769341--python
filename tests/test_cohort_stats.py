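"""Focus-week cohorts, one-sided KS test, readmission logistic models."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import jailstint as js


# ---------------------------------------------------------------------------
# cohorts

def _discharged(rows):
    """rows: (id, admit ISO, discharge ISO)"""
    df = pd.DataFrame(rows, columns=["id", "admit_dt", "discharge_dt"])
    df["admit_dt"] = pd.to_datetime(df["admit_dt"])
    df["discharge_dt"] = pd.to_datetime(df["discharge_dt"])
    df["duration_days"] = (df["discharge_dt"] - df["admit_dt"]).dt.days.astype(
        float)
    df["age_at_discharge"] = pd.array([30] * len(df), dtype="Int64")
    return df


def test_focus_week_boundaries():
    eps = _discharged([
        ("a", "2020-03-01", "2020-03-25"),   # inside
        ("b", "2020-03-01", "2020-03-23"),   # first day
        ("c", "2020-03-01", "2020-03-29"),   # last day
        ("d", "2020-03-01", "2020-03-30"),   # outside
        ("e", "2019-03-01", "2019-03-25"),   # other year
    ])
    cohorts = js.focus_week_cohorts(eps, [2019, 2020])
    assert set(cohorts[2020]["id"]) == {"a", "b", "c"}
    assert set(cohorts[2019]["id"]) == {"e"}
    with pytest.raises(ValueError, match="2018"):
        js.focus_week_cohorts(eps, [2018])


# ---------------------------------------------------------------------------
# one-sided KS

def _brute_force_ks_plus(a, b):
    """max over pooled points of F_b(x) − F_a(x), by direct counting."""
    best = 0.0
    for x in np.concatenate([a, b]):
        fa = np.mean(np.asarray(a) <= x)
        fb = np.mean(np.asarray(b) <= x)
        best = max(best, fb - fa)
    return best


def test_ks_self_comparison_zero():
    x = np.array([1.0, 2.0, 5.0, 5.0, 9.0])
    r = js.ks_one_sided(x, x)
    assert r.statistic == 0.0
    assert r.p_value == 1.0


def test_ks_disjoint_supports_one():
    r = js.ks_one_sided([4, 5, 6], [1, 2, 3])
    assert r.statistic == 1.0
    # and the reverse alternative finds no evidence
    assert js.ks_one_sided([1, 2, 3], [4, 5, 6]).statistic == 0.0


def test_ks_statistic_matches_brute_force_and_scipy():
    rng = np.random.default_rng(11)
    for trial in range(200):
        na, nb = rng.integers(2, 26, 2)
        a = rng.normal(size=na).round(2)     # rounding forces some ties
        b = rng.normal(rng.uniform(-1, 1), size=nb).round(2)
        r = js.ks_one_sided(a, b)
        assert r.statistic == pytest.approx(_brute_force_ks_plus(a, b))
        sp = stats.ks_2samp(a, b, alternative="less")
        assert r.statistic == pytest.approx(sp.statistic)


def test_ks_asymptotic_p_formula():
    rng = np.random.default_rng(4)
    a = rng.normal(1.0, 1, 400)
    b = rng.normal(0.0, 1, 300)
    r = js.ks_one_sided(a, b)
    m = 400 * 300 / 700
    assert r.p_value == pytest.approx(np.exp(-2 * m * r.statistic**2))


def test_ks_invariant_under_monotone_transform():
    rng = np.random.default_rng(5)
    a = rng.exponential(2.0, 40)
    b = rng.exponential(1.0, 35)
    d0 = js.ks_one_sided(a, b).statistic
    for f in (np.log, np.sqrt, lambda x: 3 * x + 1):
        assert js.ks_one_sided(f(a), f(b)).statistic == pytest.approx(d0)


def test_ks_exact_p_matches_permutation_monte_carlo():
    rng = np.random.default_rng(17)
    a = rng.normal(0.7, 1, 8)
    b = rng.normal(0.0, 1, 9)
    r = js.ks_one_sided(a, b, exact=True)
    pooled = np.concatenate([a, b])
    n_mc = 20000
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(pooled)
        if js.ks_one_sided(perm[:8], perm[8:]).statistic >= r.statistic - 1e-12:
            hits += 1
    mc = hits / n_mc
    se = np.sqrt(mc * (1 - mc) / n_mc)
    assert abs(r.p_value - mc) < 4 * se + 1e-3


def test_ks_empty_sample_rejected():
    with pytest.raises(ValueError, match="nonempty"):
        js.ks_one_sided([], [1.0])


# ---------------------------------------------------------------------------
# readmission flags

def test_readmission_flag_definition():
    eps = _discharged([
        ("p", "2018-01-01", "2018-03-10"),
        ("p", "2018-07-01", "2018-08-01"),   # same-year readmission for row 1
        ("q", "2018-01-01", "2018-03-10"),
        ("q", "2019-01-05", "2019-02-01"),   # next year: no readmission
        ("r", "2018-01-01", "2018-03-10"),   # no later episode
    ])
    obs = js.readmission_flags(eps)
    flags = obs.set_index(["id", "admit_dt"])["readmitted_same_year"]
    assert flags[("p", pd.Timestamp("2018-01-01"))] == 1
    assert flags[("q", pd.Timestamp("2018-01-01"))] == 0
    assert flags[("r", pd.Timestamp("2018-01-01"))] == 0


def test_readmission_same_day_admission_not_counted():
    """Readmission requires an admission strictly after the discharge."""
    eps = _discharged([
        ("p", "2018-01-01 08:00", "2018-03-10 12:00"),
        ("p", "2018-03-10 12:00", "2018-04-01 08:00"),
    ])
    obs = js.readmission_flags(eps)
    first = obs[obs["admit_dt"] == pd.Timestamp("2018-01-01 08:00")]
    assert first["readmitted_same_year"].iloc[0] == 0


def test_design_rows():
    eps = _discharged([("a", "2020-03-01", "2020-03-25"),
                       ("b", "2019-03-01", "2019-03-25"),
                       ("c", "2020-05-01", "2020-06-01"),
                       ("d", "2018-05-01", "2018-06-01")])
    obs = js.readmission_flags(eps)
    rows = obs.set_index("id")
    assert tuple(rows.loc["a", ["in_focus_week", "year_is_focus",
                                "interaction"]]) == (1, 1, 1)
    assert tuple(rows.loc["b", ["in_focus_week", "year_is_focus",
                                "interaction"]]) == (1, 0, 0)
    assert tuple(rows.loc["c", ["in_focus_week", "year_is_focus",
                                "interaction"]]) == (0, 1, 0)
    assert tuple(rows.loc["d", ["in_focus_week", "year_is_focus",
                                "interaction"]]) == (0, 0, 0)


# ---------------------------------------------------------------------------
# logistic regression

def test_intercept_only_fifty_percent():
    y = np.array([0, 1] * 50)
    X = pd.DataFrame({"intercept": np.ones(100)})
    fit = js.fit_logistic(X, y)
    assert fit.converged
    assert fit.coef("intercept") == pytest.approx(0.0, abs=1e-8)


def test_independent_covariate_near_zero():
    rng = np.random.default_rng(8)
    n = 100_000
    x = rng.integers(0, 2, n).astype(float)
    y = rng.random(n) < 0.3           # independent of x
    X = pd.DataFrame({"intercept": 1.0, "x": x})
    fit = js.fit_logistic(X, y.astype(int))
    assert abs(fit.coef("x")) < 3 * fit.se("x")


def test_parameter_recovery_and_statsmodels_agreement():
    rng = np.random.default_rng(12)
    n = 300_000
    focus = (rng.random(n) < 0.1).astype(float)
    year = (rng.random(n) < 0.15).astype(float)
    inter = focus * year
    truth = np.array([-1.0, -0.5, -0.5, -0.25])
    X = pd.DataFrame({"intercept": 1.0, "focus": focus, "year": year,
                      "interaction": inter})
    eta = X.to_numpy() @ truth
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    fit = js.fit_logistic(X, y)
    assert fit.converged
    for term, b in zip(fit.terms, truth):
        assert abs(fit.coef(term) - b) < 3 * fit.se(term)
    # independent implementation agrees to high precision
    import statsmodels.api as sm
    ref = sm.GLM(y, X.to_numpy(), family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(fit.estimates, ref.params, atol=1e-6)
    np.testing.assert_allclose(fit.std_errors, ref.bse, rtol=1e-4)


def test_deviance_decreases_across_iterations():
    rng = np.random.default_rng(2)
    n = 5000
    x = rng.normal(size=n)
    y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 + 2 * x)))).astype(int)
    fit = js.fit_logistic(pd.DataFrame({"intercept": 1.0, "x": x}), y)
    t = np.array(fit.deviance_trace)
    assert (np.diff(t) <= 1e-8).all()


def test_separation_raises():
    x = np.array([0.0] * 50 + [1.0] * 50)
    y = (x > 0.5).astype(int)          # perfectly separated
    with pytest.raises(js.SeparationError):
        js.fit_logistic(pd.DataFrame({"intercept": 1.0, "x": x}), y)


def test_readmission_models_designs_and_attenuation():
    """Adding a protective duration term attenuates the planted interaction."""
    rng = np.random.default_rng(33)
    n = 60_000
    focus = (rng.random(n) < 0.1).astype(float)
    year = (rng.random(n) < 0.15).astype(float)
    inter = focus * year
    # long stays concentrate in focus-week-2020 discharges and lower
    # readmission on their own
    dur = rng.exponential(40, n) + inter * rng.exponential(250, n)
    eta = -0.5 - 0.3 * inter - 0.004 * dur
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    discharge_year = np.where(year == 1, 2020, 2019)
    md = np.where(focus == 1, "03-25", "06-15")
    obs = pd.DataFrame({
        "id": np.arange(n).astype(str),
        "discharge_dt": pd.to_datetime(
            [f"{y_}-{m}" for y_, m in zip(discharge_year, md)]),
        "discharge_year": discharge_year,
        "in_focus_week": focus.astype(int),
        "year_is_focus": year.astype(int),
        "interaction": inter.astype(int),
        "duration_days": dur,
        "readmitted_same_year": y,
    })
    m1, m2 = js.readmission_models(obs)
    assert m1.coef("interaction") < 0
    assert m2.coef("duration") < 0
    # controlling for duration moves the interaction toward zero
    assert abs(m2.coef("interaction")) < abs(m1.coef("interaction"))
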