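"""Merging reconciled snapshots into a single episode table.

Records are matched across the admissions table (ADS), the discharges
table (DDS) and the current-custody roster on the key identifiers
(id, admission date-time, discharge date-time) and accepted in seven
categories, evaluated in order with each input row consumed at most
once:

1. full-key matches across ADS and DDS;
2. ADS rows with a missing discharge recovered from DDS via
   (id, admission);
3. DDS rows admitted before the coverage window start (absent from ADS
   by construction);
4. other DDS-only rows (presumed clerical omissions from ADS);
5. ADS-only rows that do have a discharge (presumed clerical omissions
   from DDS);
6. ADS rows with a missing discharge found in the current roster —
   ongoing episodes;
7. current-roster rows found in neither ADS nor DDS — ongoing episodes.

Each episode keeps the field values of every contributing source
(``*_a`` from ADS or the only source, ``*_b`` from a second source) so
that the cleaning stage can resolve conflicts; age at discharge is
carried from DDS where available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import pandas as pd

#: per-source field pairs kept on the episode table
PAIRED_FIELDS = ("race", "gender", "status_code", "top_charge")

EPISODE_COLUMNS = (["id", "admit_dt", "discharge_dt", "ongoing",
                    "merge_category", "age_at_discharge"]
                   + [f"{f}_a" for f in PAIRED_FIELDS]
                   + [f"{f}_b" for f in PAIRED_FIELDS])


class MergeConsistencyError(RuntimeError):
    """A key was claimed by more than one acceptance category."""


@dataclass
class MergeReport:
    category_counts: dict[int, int] = field(default_factory=dict)
    unmatched_ads: int = 0
    unmatched_current: int = 0

    @property
    def total_accepted(self) -> int:
        return sum(self.category_counts.values())

    def to_dict(self) -> dict:
        return {"categories": {str(k): v
                               for k, v in sorted(self.category_counts.items())},
                "total_accepted": self.total_accepted,
                "unmatched_ads": self.unmatched_ads,
                "unmatched_current": self.unmatched_current}


def _episode_frame(rows: pd.DataFrame, category: int, *, ongoing: bool,
                   b_source: pd.DataFrame | None = None) -> pd.DataFrame:
    out = pd.DataFrame({
        "id": rows["id"].to_numpy(),
        "admit_dt": rows["admit_dt"].to_numpy(),
        "discharge_dt": (pd.NaT if ongoing
                         else rows["discharge_dt"].to_numpy()),
        "ongoing": ongoing,
        "merge_category": category,
        "age_at_discharge": (rows["age_at_discharge"].to_numpy()
                             if "age_at_discharge" in rows
                             else pd.NA),
    })
    for f in PAIRED_FIELDS:
        out[f"{f}_a"] = rows[f].to_numpy() if f in rows else None
        out[f"{f}_b"] = (rows[f"{f}_dds"].to_numpy()
                         if f"{f}_dds" in rows else None)
    out["age_at_discharge"] = out["age_at_discharge"].astype("Int64")
    return out


def merge_records(ads: pd.DataFrame, dds: pd.DataFrame,
                  current: pd.DataFrame, data_date: date, *,
                  coverage_start: date = date(2014, 1, 1),
                  ) -> tuple[pd.DataFrame, MergeReport]:
    """Combine reconciled tables into one episode table.

    ``data_date`` is the scrape date (discharge stand-in for ongoing
    episodes, used downstream); ``coverage_start`` is the first
    admission date the admissions table covers, separating category 3
    from category 4.  Raises :class:`MergeConsistencyError` if a
    (id, admission) key would be accepted twice.
    """
    max_admit = max(t.loc[:, "admit_dt"].max() for t in (ads, dds, current)
                    if len(t))
    if pd.Timestamp(data_date) + pd.Timedelta(days=1) <= max_admit:
        raise ValueError("data_date precedes the latest admission")

    key2 = ["id", "admit_dt"]
    key3 = key2 + ["discharge_dt"]
    dds_suffixed = dds.rename(columns={f: f"{f}_dds" for f in PAIRED_FIELDS})
    parts: list[pd.DataFrame] = []
    report = MergeReport()

    # (1) full three-key matches
    ads_d = ads[ads["discharge_dt"].notna()].copy()
    cat1 = ads_d.merge(dds_suffixed[key3 + ["age_at_discharge"]
                                    + [f"{f}_dds" for f in PAIRED_FIELDS]],
                       on=key3, how="inner")
    parts.append(_episode_frame(cat1, 1, ongoing=False))
    used_dds = pd.MultiIndex.from_frame(cat1[key3])
    used_ads = pd.MultiIndex.from_frame(cat1[key2])
    dds_rest = dds_suffixed[~pd.MultiIndex.from_frame(
        dds_suffixed[key3]).isin(used_dds)]
    ads_rest = ads[~pd.MultiIndex.from_frame(ads[key2]).isin(used_ads)]

    # (2) ADS rows missing a discharge, recovered from DDS
    ads_nd = ads_rest[ads_rest["discharge_dt"].isna()].drop(
        columns="discharge_dt")
    cat2 = ads_nd.merge(
        dds_rest[key2 + ["discharge_dt", "age_at_discharge"]
                 + [f"{f}_dds" for f in PAIRED_FIELDS]],
        on=key2, how="inner")
    parts.append(_episode_frame(cat2, 2, ongoing=False))
    used2 = pd.MultiIndex.from_frame(cat2[key2])
    dds_rest = dds_rest[~pd.MultiIndex.from_frame(dds_rest[key2]).isin(used2)]
    ads_rest = ads_rest[~pd.MultiIndex.from_frame(ads_rest[key2]).isin(used2)]

    # (3) DDS-only, admitted before coverage start
    pre = dds_rest["admit_dt"] < pd.Timestamp(coverage_start)
    cat3 = dds_rest[pre].rename(
        columns={f"{f}_dds": f for f in PAIRED_FIELDS})
    parts.append(_episode_frame(cat3, 3, ongoing=False))

    # (4) remaining DDS-only rows
    cat4 = dds_rest[~pre].rename(
        columns={f"{f}_dds": f for f in PAIRED_FIELDS})
    parts.append(_episode_frame(cat4, 4, ongoing=False))

    # (5) ADS-only rows with a discharge
    ads_rest_d = ads_rest[ads_rest["discharge_dt"].notna()]
    parts.append(_episode_frame(ads_rest_d, 5, ongoing=False))

    # (6) ADS rows missing a discharge, found in the current roster
    ads_rest_nd = ads_rest[ads_rest["discharge_dt"].isna()]
    cur_keys = pd.MultiIndex.from_frame(current[key2])
    in_current = pd.MultiIndex.from_frame(ads_rest_nd[key2]).isin(cur_keys)
    parts.append(_episode_frame(ads_rest_nd[in_current], 6, ongoing=True))
    report.unmatched_ads = int((~in_current).sum())

    # (7) current-roster rows found in neither ADS nor DDS
    ads_keys = pd.MultiIndex.from_frame(ads[key2])
    dds_keys = pd.MultiIndex.from_frame(dds[key2])
    cur_idx = pd.MultiIndex.from_frame(current[key2])
    only = ~cur_idx.isin(ads_keys) & ~cur_idx.isin(dds_keys)
    parts.append(_episode_frame(current[only], 7, ongoing=True))
    report.unmatched_current = int(len(current) - only.sum()
                                   - len(parts[5]))  # consumed by cat 6

    episodes = pd.concat(parts, ignore_index=True)
    for cat in range(1, 8):
        report.category_counts[cat] = int(
            (episodes["merge_category"] == cat).sum())

    dup = episodes.duplicated(subset=key2)
    if dup.any():
        raise MergeConsistencyError(
            f"{int(dup.sum())} (id, admission) keys accepted more than once")
    return episodes, report
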