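"""Reading raw snapshot tables and reconciling erroneous records.

Admission and discharge snapshots published by an open-data portal
overlap but disagree: exact duplicates, near-duplicate rows that
conflict on the discharge date-time, records whose discharge precedes
their admission, and cross-file discharge conflicts.  ``reconcile``
removes four categories of irreparable records and reports exactly what
was removed:

1. exact duplicate rows (keep one);
2. groups of discharge-table rows sharing (id, admission) but
   conflicting on the discharge date-time (all members removed — with
   no principled tie-break, keeping one would fabricate data);
3. rows whose discharge precedes the admission by more than one
   calendar day (same-day and previous-day inversions are clock slips
   repaired later during cleaning, not removed);
4. discharge-table rows that match an admissions row on (id, admission)
   but conflict on a non-missing discharge (the admissions copy is
   kept).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .synthetic_data import (ADS_COLUMNS, CURRENT_COLUMNS, DDS_COLUMNS,
                             PORTAL_COLUMN_MAP)

SOURCES = ("ADS", "DDS", "CURRENT")

_SOURCE_COLUMNS = {"ADS": ADS_COLUMNS, "DDS": DDS_COLUMNS,
                   "CURRENT": CURRENT_COLUMNS}


class IngestError(ValueError):
    """Raised for unparseable or structurally invalid raw rows."""


def read_raw_table(path: str | Path, source_tag: str, *,
                   column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read one snapshot CSV into the canonical typed schema.

    ``column_map`` maps canonical field names to the CSV's header names
    (defaulting to the portal dialect).  Empty cells become missing
    values; date-times are parsed to minute resolution.  A missing
    id/admission or an unparseable date-time raises :class:`IngestError`
    naming the offending data row (1-based).
    """
    if source_tag not in SOURCES:
        raise ValueError(f"source_tag must be one of {SOURCES}")
    column_map = column_map or PORTAL_COLUMN_MAP
    wanted = _SOURCE_COLUMNS[source_tag]
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame = pd.DataFrame(index=raw.index)
    for canon in wanted:
        header = column_map.get(canon, canon)
        if header in raw.columns:
            col = raw[header].replace("", None)
        elif canon in raw.columns:
            col = raw[canon].replace("", None)
        elif canon in ("discharge_dt", "age_at_discharge"):
            col = pd.Series(None, index=raw.index, dtype=object)
        else:
            raise IngestError(f"{source_tag}: missing required column "
                              f"{header!r}")
        frame[canon] = col

    for dt_col in ("admit_dt", "discharge_dt"):
        if dt_col not in frame:
            continue
        parsed = pd.to_datetime(frame[dt_col], format="ISO8601",
                                errors="coerce")
        bad = parsed.isna() & frame[dt_col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise IngestError(f"{source_tag} row {row}: unparseable "
                             f"{dt_col} {frame[dt_col][bad.idxmax()]!r}")
        frame[dt_col] = parsed.dt.floor("min")

    missing_key = frame["id"].isna() | frame["admit_dt"].isna()
    if missing_key.any():
        row = int(missing_key.idxmax()) + 1
        raise IngestError(f"{source_tag} row {row}: missing id or "
                          "admission date-time")
    frame["id"] = frame["id"].astype(str)

    if "age_at_discharge" in frame:
        age = pd.to_numeric(frame["age_at_discharge"], errors="coerce")
        bad = age.isna() & frame["age_at_discharge"].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise IngestError(f"{source_tag} row {row}: unparseable age")
        frame["age_at_discharge"] = age.astype("Int64")
    frame["source"] = source_tag
    return frame


@dataclass
class RemovalReport:
    """Counts and row references for the four reconciliation removals."""

    exact_duplicate: int = 0
    conflicting_dds: int = 0
    gross_inversion: int = 0
    cross_file_conflict: int = 0
    removed_rows: dict[str, list[int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"exact_duplicate": self.exact_duplicate,
                "conflicting_dds": self.conflicting_dds,
                "gross_inversion": self.gross_inversion,
                "cross_file_conflict": self.cross_file_conflict}

    @property
    def total_removed(self) -> int:
        return sum(self.to_dict().values())


def _gross_inversion_mask(frame: pd.DataFrame) -> pd.Series:
    """Discharge date more than one calendar day before the admission date."""
    both = frame["discharge_dt"].notna()
    gap = (frame["discharge_dt"].dt.normalize()
           - frame["admit_dt"].dt.normalize()).dt.days
    return both & (gap < -1)


def reconcile(ads: pd.DataFrame,
              dds: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame,
                                          RemovalReport]:
    """Apply the four removal categories to ingested ADS/DDS tables.

    Returns the surviving tables (original index preserved) and a
    :class:`RemovalReport`.  The operation is idempotent.
    """
    report = RemovalReport()
    removed: dict[str, list[int]] = {"ADS": [], "DDS": []}
    key = ["id", "admit_dt"]
    data_cols_ads = [c for c in ADS_COLUMNS if c in ads.columns]
    data_cols_dds = [c for c in DDS_COLUMNS if c in dds.columns]

    # (1) exact duplicates: keep the first copy
    dup_ads = ads.duplicated(subset=data_cols_ads, keep="first")
    dup_dds = dds.duplicated(subset=data_cols_dds, keep="first")
    report.exact_duplicate = int(dup_ads.sum()) + int(dup_dds.sum())
    removed["ADS"] += list(ads.index[dup_ads])
    removed["DDS"] += list(dds.index[dup_dds])
    ads = ads[~dup_ads]
    dds = dds[~dup_dds]

    # (2) conflicting DDS groups on (id, admit): all members removed
    n_discharges = dds.groupby(key)["discharge_dt"].transform("nunique",
                                                              dropna=False)
    conflict = n_discharges > 1
    report.conflicting_dds = int(conflict.sum())
    removed["DDS"] += list(dds.index[conflict])
    dds = dds[~conflict]

    # (3) gross date inversions in either table
    for name, frame in (("ADS", ads), ("DDS", dds)):
        mask = _gross_inversion_mask(frame)
        report.gross_inversion += int(mask.sum())
        removed[name] += list(frame.index[mask])
        if name == "ADS":
            ads = frame[~mask]
        else:
            dds = frame[~mask]

    # (4) DDS rows conflicting with ADS on a non-missing discharge
    ads_key = ads.loc[ads["discharge_dt"].notna(),
                      key + ["discharge_dt"]].rename(
        columns={"discharge_dt": "_ads_discharge"})
    probe = dds.reset_index().merge(ads_key, on=key, how="left")
    conflict = (probe["_ads_discharge"].notna()
                & probe["discharge_dt"].notna()
                & (probe["_ads_discharge"] != probe["discharge_dt"]))
    bad_idx = probe.loc[conflict, "index"].unique()
    report.cross_file_conflict = int(len(bad_idx))
    removed["DDS"] += list(bad_idx)
    dds = dds[~dds.index.isin(bad_idx)]

    report.removed_rows = removed
    return ads, dds, report
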