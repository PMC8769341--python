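"""Focus-week cohort comparisons and readmission models.

The focus week is a month-day span (default March 23-29).  Episodes
discharged inside it are compared across years with one-sided
two-sample Kolmogorov-Smirnov tests (stay duration, age at discharge)
and with logistic regressions of same-calendar-year readmission on
focus-week, year and interaction indicators, optionally with a stay
duration fixed effect.

The one-sided KS statistic for the alternative "sample A is
stochastically larger" is D+ = sup_x [F_B(x) − F_A(x)]; its asymptotic
p-value is exp(−2 m D+²) with m = n_a n_b / (n_a + n_b).  An exact
small-sample p-value is available by lattice-path counting for
tie-free samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

FOCUS_WEEK_DEFAULT = ((3, 23), (3, 29))   # month-day span, inclusive


# ---------------------------------------------------------------------------
# cohorts

def _in_month_day_window(ts: pd.Series, window) -> pd.Series:
    (m0, d0), (m1, d1) = window
    md = ts.dt.month * 100 + ts.dt.day
    return (md >= m0 * 100 + d0) & (md <= m1 * 100 + d1)


def focus_week_cohorts(episodes: pd.DataFrame, years,
                       month_day_window=FOCUS_WEEK_DEFAULT,
                       ) -> dict[int, pd.DataFrame]:
    """Episodes discharged in the focus week, split by year.

    Raises if any requested year has an empty cohort.
    """
    discharged = episodes[episodes["discharge_dt"].notna()]
    in_week = _in_month_day_window(discharged["discharge_dt"],
                                   month_day_window)
    week = discharged[in_week]
    out = {}
    for year in years:
        cohort = week[week["discharge_dt"].dt.year == year]
        if cohort.empty:
            raise ValueError(f"no focus-week discharges in {year}")
        out[int(year)] = cohort.reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# one-sided Kolmogorov-Smirnov

@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float
    alternative: str
    n_a: int
    n_b: int


def _ks_plus_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """sup_x [F_b(x) − F_a(x)] over the pooled sample points."""
    pooled = np.concatenate([a, b])
    fa = np.searchsorted(np.sort(a), pooled, side="right") / len(a)
    fb = np.searchsorted(np.sort(b), pooled, side="right") / len(b)
    return float(max((fb - fa).max(), 0.0))


def ks_exact_p(a, b, statistic: float) -> float:
    """Exact one-sided p-value P(D+ >= d) by lattice-path counting.

    Valid for tie-free pooled samples: counts the orderings whose
    running ECDF difference stays below ``statistic`` everywhere and
    complements.  Cost O(n_a · n_b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if len(np.unique(pooled)) != len(pooled):
        raise ValueError("exact p-value requires tie-free samples")
    na, nb = len(a), len(b)
    d = statistic - 1e-12
    # paths[i][j]: orderings of i a-values and j b-values seen so far with
    # j/nb − i/na < d at every step
    paths = np.zeros((na + 1, nb + 1), dtype=float)
    paths[0, 0] = 1.0
    for i in range(na + 1):
        for j in range(nb + 1):
            if i == 0 and j == 0:
                continue
            if j / nb - i / na >= d:
                continue
            paths[i, j] = (paths[i - 1, j] if i else 0.0) + \
                          (paths[i, j - 1] if j else 0.0)
    return float(1.0 - paths[na, nb] / comb(na + nb, na))


def ks_one_sided(sample_a, sample_b, alternative: str = "a_larger",
                 exact: bool = False) -> KSResult:
    """One-sided two-sample KS test.

    ``alternative='a_larger'`` tests H1 that the CDF of A lies below
    the CDF of B (A stochastically larger); ``'b_larger'`` swaps the
    roles.  The p-value is the asymptotic bound exp(−2 m D²) unless
    ``exact`` is set (small tie-free samples).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    if alternative == "a_larger":
        d = _ks_plus_statistic(a, b)
    elif alternative == "b_larger":
        d = _ks_plus_statistic(b, a)
    else:
        raise ValueError("alternative must be 'a_larger' or 'b_larger'")
    m = len(a) * len(b) / (len(a) + len(b))
    if exact:
        p = (ks_exact_p(a, b, d) if alternative == "a_larger"
             else ks_exact_p(b, a, d))
    else:
        p = float(np.exp(-2.0 * m * d * d))
    return KSResult(statistic=d, p_value=min(p, 1.0),
                    alternative=alternative, n_a=len(a), n_b=len(b))


# ---------------------------------------------------------------------------
# readmission observations

def readmission_flags(episodes: pd.DataFrame, *,
                      focus_year: int = 2020,
                      month_day_window=FOCUS_WEEK_DEFAULT) -> pd.DataFrame:
    """One observation per discharged episode with readmission outcome.

    ``readmitted_same_year`` is 1 iff the same individual has another
    admission strictly after this discharge with an admission date in
    the same calendar year.  Indicator columns mark discharge in the
    focus week, in the focus year, and their interaction.
    """
    obs = episodes[episodes["discharge_dt"].notna()].copy()
    obs = obs.sort_values(["id", "admit_dt"]).reset_index(drop=True)

    readmitted = np.zeros(len(obs), dtype=np.int8)
    for _, group in obs.groupby("id", sort=False):
        admits = group["admit_dt"].to_numpy()
        discharges = group["discharge_dt"].to_numpy()
        years = group["discharge_dt"].dt.year.to_numpy()
        admit_years = group["admit_dt"].dt.year.to_numpy()
        idx = group.index.to_numpy()
        for k in range(len(group)):
            later = (admits > discharges[k]) & (admit_years == years[k])
            if later.any():
                readmitted[idx[k]] = 1

    obs["readmitted_same_year"] = readmitted
    obs["discharge_year"] = obs["discharge_dt"].dt.year
    obs["in_focus_week"] = _in_month_day_window(
        obs["discharge_dt"], month_day_window).astype(int)
    obs["year_is_focus"] = (obs["discharge_year"] == focus_year).astype(int)
    obs["interaction"] = obs["in_focus_week"] * obs["year_is_focus"]
    return obs


# ---------------------------------------------------------------------------
# logistic regression (IRLS with step halving)

class SeparationError(RuntimeError):
    """The likelihood is unbounded (perfect separation) or the fit diverged."""


@dataclass
class LogisticFit:
    terms: list[str]
    estimates: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    converged: bool
    n_obs: int
    deviance: float
    n_iter: int
    deviance_trace: list[float] | None = None

    def coef(self, term: str) -> float:
        return float(self.estimates[self.terms.index(term)])

    def se(self, term: str) -> float:
        return float(self.std_errors[self.terms.index(term)])

    def summary_frame(self) -> pd.DataFrame:
        stars = np.select(
            [self.p_values < 1e-3, self.p_values < 1e-2, self.p_values < 5e-2],
            ["***", "**", "*"], default="")
        return pd.DataFrame({"Variable": self.terms,
                             "Estimate": self.estimates,
                             "Standard Error": self.std_errors,
                             "p": self.p_values, "": stars})


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    eps = 1e-12
    return float(-2.0 * np.sum(y * np.log(mu + eps)
                               + (1 - y) * np.log(1 - mu + eps)))


def fit_logistic(design: pd.DataFrame | np.ndarray, outcome,
                 tol: float = 1e-8, max_iter: int = 100) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS.

    Newton steps with step halving keep the deviance non-increasing;
    convergence when the largest absolute coefficient update falls
    below ``tol``.  Standard errors come from the inverse observed
    information.  Perfect separation (diverging coefficients) raises
    :class:`SeparationError`.
    """
    if isinstance(design, pd.DataFrame):
        terms = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        terms = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")

    beta = np.zeros(X.shape[1])
    mu = np.full(len(y), 0.5)
    dev = _deviance(y, mu)
    trace = [dev]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        W = mu * (1 - mu)
        XtWX = X.T @ (X * W[:, None])
        score = X.T @ (y - mu)
        try:
            step = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError as e:
            raise SeparationError(f"information matrix singular: {e}") from e
        # step halving: accept only deviance-non-increasing updates
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            eta = np.clip(X @ cand, -35, 35)
            mu_cand = 1.0 / (1.0 + np.exp(-eta))
            dev_cand = _deviance(y, mu_cand)
            if dev_cand <= dev + 1e-10:
                break
            scale /= 2.0
        beta_new = beta + scale * step
        update = np.abs(scale * step).max()
        beta, mu, dev = beta_new, mu_cand, dev_cand
        trace.append(dev)
        if update < tol:
            converged = True
            break

    if np.abs(beta).max() > 30:
        raise SeparationError("coefficients diverged; data likely separated")
    W = mu * (1 - mu)
    cov = np.linalg.inv(X.T @ (X * W[:, None]))
    se = np.sqrt(np.diag(cov))
    from scipy.stats import norm
    z = beta / se
    p = 2 * norm.sf(np.abs(z))
    return LogisticFit(terms=terms, estimates=beta, std_errors=se,
                       p_values=p, converged=converged, n_obs=len(y),
                       deviance=dev, n_iter=it, deviance_trace=trace)


def readmission_models(observations: pd.DataFrame,
                       ) -> tuple[LogisticFit, LogisticFit]:
    """Fit the two readmission models.

    Model 1: readmitted ~ intercept + focus_week + focus_year +
    interaction.  Model 2 adds the stay duration in days.  Requires
    observations from at least two years including the focus year.
    """
    years = observations["discharge_year"].unique()
    if len(years) < 2 or observations["year_is_focus"].sum() == 0:
        raise ValueError("observations must span at least two years "
                         "including the focus year")
    base = pd.DataFrame({
        "intercept": 1.0,
        "focus_week": observations["in_focus_week"].astype(float),
        "year2020": observations["year_is_focus"].astype(float),
        "interaction": observations["interaction"].astype(float),
    })
    y = observations["readmitted_same_year"].to_numpy()
    model1 = fit_logistic(base, y)
    base2 = base.assign(duration=observations["duration_days"].astype(float))
    model2 = fit_logistic(base2, y)
    return model1, model2
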