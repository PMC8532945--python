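"""The two utilization responses: squares/h and per-square usage frequency.

Response 1 (one value per horse-day): the number of distinct 3 x 3 m
squares a horse occupies per clock hour, averaged over hours with
adequate coverage.  A day needs at least 12 h of recording -- 4320 fixes
at one fix per 10 s -- to enter the analysis; the boundary is inclusive.

Response 2 (one value per square-day): the percentage of the day's fixes
(all horses pooled) that fall in the square.  Per day these percentages
sum to 100 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .farm_geometry import (FarmLayout, GridSpec, assign_label_grid,
                            project_to_local, square_of)
from .logger_io import day_index_of
from .synthetic_herd import DEFAULT_START_DATE

#: minimum fixes for a day to be included: 12 h at one fix per 10 s
MIN_FIXES_PER_DAY = int(12 * 3600 / 10)  # = 4320

#: fraction of an hour's expected fixes required for the hour to qualify
HOUR_COVERAGE = 0.90


class UndefinedResponseError(ValueError):
    """No qualifying hour: the horse-day has no defined response."""


@dataclass
class HorseDayUsage:
    """Model-1 response for one horse-day and dataset variant."""

    horse_id: int
    day: int
    variant: str                  # "with_pasture" | "paddock_only"
    hours_covered: int
    n_fixes: int
    squares_per_hour: float
    included: bool


def _square_codes(day_fixes: pd.DataFrame, grid: GridSpec, origin) -> np.ndarray:
    x, y = project_to_local(day_fixes["lat"].to_numpy(),
                            day_fixes["lon"].to_numpy(), origin)
    rows, cols = square_of(x, y, grid)
    return grid.encode(rows, cols)


def squares_per_hour(day_fixes: pd.DataFrame, grid: GridSpec, layout: FarmLayout,
                     day: int, variant: str = "with_pasture",
                     fix_interval: float = 10.0,
                     hour_coverage: float = HOUR_COVERAGE,
                     method: str = "per_hour") -> HorseDayUsage:
    """Distinct squares visited per hour for one horse-day.

    ``method="per_hour"`` (default): count distinct squares within each
    local clock hour holding at least ``hour_coverage`` of its expected
    fixes, then average over those qualifying hours.  A square revisited
    in two hours counts in both.  ``method="per_day_ratio"`` instead
    divides the day's total distinct-square count by the qualifying-hour
    count.  Raises :class:`UndefinedResponseError` with zero qualifying
    hours.
    """
    if method not in ("per_hour", "per_day_ratio"):
        raise ValueError(f"unknown method {method!r}")
    n_fixes = len(day_fixes)
    expected = 3600.0 / fix_interval
    min_per_hour = int(np.ceil(hour_coverage * expected))

    codes = _square_codes(day_fixes, grid, layout.projection_origin)
    hours = pd.to_datetime(day_fixes["timestamp_local"]).dt.hour.to_numpy()
    per_hour = pd.DataFrame({"hour": hours, "code": codes}).groupby("hour")["code"]
    counts = per_hour.size()
    qualifying = counts.index[counts >= min_per_hour]
    if len(qualifying) == 0:
        raise UndefinedResponseError(
            f"horse-day has no hour with >= {min_per_hour} fixes")
    if method == "per_hour":
        distinct = per_hour.nunique()
        value = float(distinct.loc[qualifying].mean())
    else:
        in_q = np.isin(hours, qualifying)
        value = float(len(np.unique(codes[in_q])) / len(qualifying))
    hid = int(day_fixes["horse_id"].iloc[0])
    return HorseDayUsage(
        horse_id=hid, day=day, variant=variant,
        hours_covered=int(len(qualifying)), n_fixes=n_fixes,
        squares_per_hour=value, included=day_inclusion(n_fixes),
    )


def day_inclusion(n_fixes: int, min_fixes: int = MIN_FIXES_PER_DAY) -> bool:
    """A day enters the analysis iff it holds at least 12 h of fixes.

    At one fix per 10 s that is 4320 observations; exactly 4320 is in.
    Applied separately per dataset variant on the variant's retained fixes.
    """
    return n_fixes >= min_fixes


def build_usage_table(fixes: pd.DataFrame, grid: GridSpec, layout: FarmLayout,
                      variant: str = "with_pasture",
                      start_date: date = DEFAULT_START_DATE,
                      fix_interval: float = 10.0,
                      hour_coverage: float = HOUR_COVERAGE,
                      method: str = "per_hour") -> pd.DataFrame:
    """Model-1 response table: one row per horse-day (filtered fixes in).

    Horse-days with no qualifying hour are dropped (reason counted in the
    ``n_undefined`` attribute of the returned frame).
    """
    if len(fixes) == 0:
        table = pd.DataFrame(columns=["horse_id", "day", "variant",
                                      "hours_covered", "n_fixes",
                                      "squares_per_hour", "included"])
        table.attrs["n_undefined"] = 0
        return table
    expected = 3600.0 / fix_interval
    min_per_hour = int(np.ceil(hour_coverage * expected))
    codes = _square_codes(fixes, grid, layout.projection_origin)
    ts = pd.to_datetime(fixes["timestamp_local"])
    start = pd.Timestamp(start_date)
    work = pd.DataFrame({
        "horse_id": fixes["horse_id"].to_numpy(),
        "day": (ts.dt.normalize() - start).dt.days.to_numpy() + 1,
        "hour": ts.dt.hour.to_numpy(),
        "code": codes,
    })
    per_hour = (work.groupby(["horse_id", "day", "hour"])["code"]
                .agg(n="size", distinct="nunique"))
    per_hour["qual"] = per_hour["n"] >= min_per_hour
    by_day = per_hour.groupby(level=["horse_id", "day"])
    n_fixes = by_day["n"].sum()
    hours_covered = by_day["qual"].sum()
    if method == "per_hour":
        q = per_hour.loc[per_hour["qual"]]
        value = q.groupby(level=["horse_id", "day"])["distinct"].mean()
    elif method == "per_day_ratio":
        qual_keys = per_hour.index[per_hour["qual"]]
        sel = work.set_index(["horse_id", "day", "hour"]).loc[
            work.set_index(["horse_id", "day", "hour"]).index.isin(qual_keys)]
        distinct_day = sel.groupby(level=["horse_id", "day"])["code"].nunique()
        value = distinct_day / hours_covered.loc[distinct_day.index]
    else:
        raise ValueError(f"unknown method {method!r}")
    table = pd.DataFrame({
        "hours_covered": hours_covered.astype(int),
        "n_fixes": n_fixes.astype(int),
        "squares_per_hour": value,
    })
    n_undefined = int(table["squares_per_hour"].isna().sum())
    table = table.dropna(subset=["squares_per_hour"]).reset_index()
    table.insert(2, "variant", variant)
    table["included"] = table["n_fixes"] >= MIN_FIXES_PER_DAY
    table = table[["horse_id", "day", "variant", "hours_covered",
                   "n_fixes", "squares_per_hour", "included"]]
    table.attrs["n_undefined"] = n_undefined
    return table


def square_frequencies(all_fixes_of_day: pd.DataFrame, grid: GridSpec,
                       layout: FarmLayout, day: int,
                       label_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Per-square usage percentages of one day (all horses pooled).

    ``frequency = 100 * fixes_in_square / total_fixes_of_day``; only
    visited squares are materialised.  Frequencies sum to 100 per day.
    """
    if len(all_fixes_of_day) == 0:
        raise UndefinedResponseError("empty day: frequencies undefined")
    if label_grid is None:
        label_grid = assign_label_grid(layout, grid)
    codes = _square_codes(all_fixes_of_day, grid, layout.projection_origin)
    uniq, counts = np.unique(codes, return_counts=True)
    rows, cols = grid.decode(uniq)
    return pd.DataFrame({
        "day": day,
        "row": rows,
        "col": cols,
        "frequency": 100.0 * counts / counts.sum(),
        "location": label_grid[rows, cols],
    })


def build_frequency_table(fixes: pd.DataFrame, grid: GridSpec,
                          layout: FarmLayout,
                          start_date: date = DEFAULT_START_DATE) -> pd.DataFrame:
    """Model-2 response table: one row per visited (square, day)."""
    label_grid = assign_label_grid(layout, grid)
    local_date = pd.to_datetime(fixes["timestamp_local"]).dt.date
    parts = []
    for d, grp in fixes.groupby(local_date, sort=True):
        parts.append(square_frequencies(grp, grid, layout,
                                        day_index_of(d, start_date), label_grid))
    return pd.concat(parts, ignore_index=True)


def visited_square_count(frequency_table: pd.DataFrame) -> int:
    """Size of the visited-square universe across the whole study."""
    return int(frequency_table.groupby(["row", "col"]).ngroups)


def location_usage(frequency_table: pd.DataFrame, layout: FarmLayout,
                   grid: GridSpec) -> pd.Series:
    """Mean daily usage frequency per location label.

    Convention: for each day, the label's frequency is the mean over all
    of the label's squares (unvisited squares count as zero); values are
    then averaged over days.  Labels with zero squares in the layout are
    absent from the result, not reported as zero.
    """
    label_grid = assign_label_grid(layout, grid)
    labels, n_squares = np.unique(label_grid[label_grid != None], # noqa: E711
                                  return_counts=True)
    size = pd.Series(n_squares, index=labels, dtype=float)
    per_day = (frequency_table.groupby(["day", "location"])["frequency"]
               .sum().unstack(fill_value=0.0))
    per_day = per_day.reindex(columns=size.index, fill_value=0.0)
    return (per_day / size).mean(axis=0).rename("mean_frequency")
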