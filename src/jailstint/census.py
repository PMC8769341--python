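"""Daily population census and weekly net change.

The daily census counts, for each date in a window, the episodes whose
stay covers that date under a half-open convention: a person is counted
from their admission date up to but not including their effective
discharge date (ongoing episodes run to the data date).  The half-open
choice makes the census summed over a window exactly equal to the sum
of window-clipped date-level durations (person-days), and a same-day
stay contributes no census days.

Weeks run Monday-Sunday; the net change of a week is the census on its
Sunday minus the census on the previous Sunday, so the weekly changes
telescope to the census difference across the series.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd


@dataclass
class WeeklyChangeSeries:
    """Net weekly population change with z-scores against all weeks."""

    table: pd.DataFrame  # columns: week_start (Monday), net_change, zscore

    @property
    def minimum_week(self) -> pd.Timestamp:
        t = self.table
        return t.loc[t["net_change"].idxmin(), "week_start"]


def daily_census(episodes: pd.DataFrame, window: tuple[date, date],
                 data_date: date) -> pd.Series:
    """Headcount per day over ``window`` (both ends inclusive).

    Membership on day d: admission date <= d < effective discharge
    date.  Requires cleaned episodes carrying
    ``effective_discharge_date``; raises if the window extends past the
    data date.
    """
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    if start > end:
        raise ValueError("window start must not follow window end")
    if end > pd.Timestamp(data_date):
        raise ValueError("census window extends beyond the data date")
    days = pd.date_range(start, end, freq="D")
    counts = np.zeros(len(days) + 1, dtype=np.int64)
    if len(episodes):
        admit = episodes["admit_dt"].dt.normalize()
        leave = episodes["effective_discharge_date"]
        lo = ((admit - start).dt.days).clip(lower=0)
        hi = ((leave - start).dt.days).clip(upper=len(days))
        valid = (lo < hi) & (lo < len(days)) & (hi > 0)
        np.add.at(counts, lo[valid].to_numpy(), 1)
        np.add.at(counts, hi[valid].to_numpy(), -1)
    series = pd.Series(np.cumsum(counts[:-1]), index=days, name="headcount")
    return series


def weekly_net_change(census: pd.Series) -> WeeklyChangeSeries:
    """Weekly (Monday-Sunday) net change with z-scores.

    For each week whose Sunday and whose previous Sunday both lie in
    the series, net change = census(Sunday) − census(previous Sunday).
    Raises if fewer than two such weeks exist.
    """
    sundays = census.index[census.index.weekday == 6]
    if len(sundays) < 3:
        raise ValueError("census must span at least two full "
                         "Monday-Sunday weeks")
    values = census[sundays].to_numpy()
    change = np.diff(values)
    week_start = sundays[1:] - pd.Timedelta(days=6)
    sd = change.std(ddof=1)
    z = (change - change.mean()) / sd if sd > 0 else np.zeros_like(
        change, dtype=float)
    table = pd.DataFrame({"week_start": week_start, "net_change": change,
                          "zscore": z})
    return WeeklyChangeSeries(table=table)
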