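"""Reading, validating and splitting raw GPS-logger records.

Canonical logger CSV dialect (fixed by this package; real logger exports
can be adapted via a column-mapping):

    horse_id,timestamp_local,timestamp_utc,lat,lon,height_m,speed_kmh,step_distance_m

Comma-separated, ISO-8601 naive timestamps, period decimal separator.
Parsing is locale-independent.  One row is one fix; the nominal cadence
is one fix per 10 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

#: canonical column order of logger CSVs and in-memory fix tables
FIX_COLUMNS = [
    "horse_id",
    "timestamp_local",
    "timestamp_utc",
    "lat",
    "lon",
    "height_m",
    "speed_kmh",
    "step_distance_m",
]

_NUMERIC = ["horse_id", "lat", "lon", "height_m", "speed_kmh", "step_distance_m"]
_TIMES = ["timestamp_local", "timestamp_utc"]


class LoggerFormatError(ValueError):
    """The file does not carry the mandatory logger columns."""


@dataclass
class ReadReport:
    """Row-level outcome of one logger-CSV read."""

    n_rows: int = 0
    n_valid: int = 0
    n_errors: int = 0
    error_lines: list[int] = field(default_factory=list)  # 1-based file lines


def write_logger_csv(fixes: pd.DataFrame, path) -> None:
    """Write a fix table in the canonical dialect (lat/lon to ~0.1 mm)."""
    out = fixes[FIX_COLUMNS].copy()
    for c in _TIMES:
        out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, float_format="%.9f")


def read_logger_csv(path, id_assignment: dict[int, int] | None = None
                    ) -> tuple[pd.DataFrame, ReadReport]:
    """Read a logger CSV, validating every row.

    Malformed rows (unparseable numbers or timestamps, missing values) are
    counted and their 1-based file line numbers reported -- never silently
    dropped.  ``id_assignment`` optionally remaps horse ids (the anonymising
    "randomly ascending number" assignment).

    Raises :class:`LoggerFormatError` when a mandatory column is absent.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in FIX_COLUMNS if c not in raw.columns]
    if missing:
        raise LoggerFormatError(f"missing mandatory column(s): {', '.join(missing)}")

    report = ReadReport(n_rows=len(raw))
    if len(raw) == 0:
        empty = pd.DataFrame({c: pd.Series(dtype="datetime64[ns]") if c in _TIMES
                              else pd.Series(dtype=float) for c in FIX_COLUMNS})
        empty["horse_id"] = empty["horse_id"].astype(np.int64)
        report.n_valid = 0
        return empty[FIX_COLUMNS], report

    conv = pd.DataFrame(index=raw.index)
    for c in _NUMERIC:
        conv[c] = pd.to_numeric(raw[c], errors="coerce")
    for c in _TIMES:
        conv[c] = pd.to_datetime(raw[c], errors="coerce", format="ISO8601")
    bad = conv[FIX_COLUMNS[:1] + _TIMES + ["lat", "lon"]].isna().any(axis=1)
    bad |= ~np.isfinite(conv[["lat", "lon"]]).all(axis=1)

    report.n_errors = int(bad.sum())
    report.error_lines = [int(i) + 2 for i in conv.index[bad]]  # +2: header + 1-based
    report.n_valid = report.n_rows - report.n_errors

    out = conv.loc[~bad, FIX_COLUMNS].reset_index(drop=True)
    out["horse_id"] = out["horse_id"].astype(np.int64)
    if id_assignment:
        out["horse_id"] = out["horse_id"].map(lambda h: id_assignment.get(h, h))
    return out, report


def split_horse_days(fixes: pd.DataFrame) -> dict[tuple[int, date], pd.DataFrame]:
    """Partition a fix table into per-(horse, local calendar day) streams.

    The husbandry day is the local calendar date.  No fix is lost or
    duplicated; each group is time-sorted.
    """
    if len(fixes) == 0:
        return {}
    local_date = pd.to_datetime(fixes["timestamp_local"]).dt.date
    groups = {}
    for (hid, d), grp in fixes.groupby([fixes["horse_id"], local_date], sort=True):
        groups[(int(hid), d)] = grp.sort_values("timestamp_utc").reset_index(drop=True)
    return groups


def day_index_of(local_date: date, start_date: date) -> int:
    """1-based observation-day index of a local calendar date."""
    return (local_date - start_date).days + 1
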