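"""Cleaning cascade for raw fix streams.

Order is fixed and documented: (1) farm bounding-box clip, (2) sequential
speed / step-distance outlier removal, (3) clip to paddock (and optionally
pasture) polygons.  Step distances are recomputed from coordinates by
great-circle distance -- the device's own distance column is kept only
for audit -- so the filter stays consistent with the projection used for
gridding.

The speed/step stage is sequential: each fix is tested against the last
*retained* fix, so one teleport spike cannot cascade into removals of
the valid fixes that follow it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .farm_geometry import FarmLayout, haversine_m, project_to_local

#: physiological thresholds: horses do not exceed 50 km/h, nor 140 m / 10 s
MAX_SPEED_KMH = 50.0
MAX_STEP_M_PER_10S = 140.0

#: a horse-day losing more than this fraction of its rows to malformed
#: parses or filter removals is treated as a demolished/ill-adjusted logger
DEMOLISHED_FRACTION = 0.20


@dataclass
class FilterReport:
    """Per-rule removal counts of one cascade run."""

    n_input: int = 0
    removed_bbox: int = 0
    removed_speed: int = 0
    removed_step: int = 0
    removed_outside_area: int = 0
    n_retained: int = 0

    @property
    def n_removed(self) -> int:
        return (self.removed_bbox + self.removed_speed
                + self.removed_step + self.removed_outside_area)

    def check(self) -> None:
        assert self.n_removed + self.n_retained == self.n_input


def clip_bounding_box(fixes: pd.DataFrame, layout: FarmLayout
                      ) -> tuple[pd.DataFrame, int]:
    """Drop fixes outside the farm's geodetic bounding box (order kept)."""
    lat_min, lat_max, lon_min, lon_max = layout.bounding_box_geodetic()
    lat = fixes["lat"].to_numpy()
    lon = fixes["lon"].to_numpy()
    inside = (lat >= lat_min) & (lat <= lat_max) & (lon >= lon_min) & (lon <= lon_max)
    return fixes.loc[inside].reset_index(drop=True), int((~inside).sum())


def _scan_stream(lat, lon, t_s, max_speed_kmh, max_step_m):
    """Sequential anchor scan of one time-sorted stream.

    Returns (keep mask, n_removed_step, n_removed_speed).  The distance
    threshold scales with the time gap (max_step_m per 10 s); a fix is
    removed when its recomputed distance from the previous retained fix
    exceeds the scaled threshold or implies more than max_speed_kmh.
    """
    n = len(lat)
    keep = np.ones(n, dtype=bool)
    n_step = n_speed = 0
    if n < 2:
        return keep, n_step, n_speed

    # fast path: consecutive distances; only indices violating a consecutive
    # test can ever violate the sequential test while the anchor tracks i-1
    d_consec = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
    gap_consec = np.maximum(np.diff(t_s), 1e-9)
    viol = (d_consec > max_step_m * gap_consec / 10.0) | \
           (d_consec / gap_consec * 3.6 > max_speed_kmh)
    cand = np.flatnonzero(viol) + 1
    if len(cand) == 0:
        return keep, n_step, n_speed

    anchor = 0
    i = 1
    ci = 0  # pointer into cand
    while i < n:
        if anchor == i - 1:
            # consecutive case: jump to the next precomputed violation
            while ci < len(cand) and cand[ci] < i:
                ci += 1
            if ci == len(cand):
                break
            nxt = cand[ci]
            anchor = nxt - 1
            i = nxt
        gap = max(t_s[i] - t_s[anchor], 1e-9)
        d = float(haversine_m(lat[anchor], lon[anchor], lat[i], lon[i]))
        if d > max_step_m * gap / 10.0:
            keep[i] = False
            n_step += 1
        elif d / gap * 3.6 > max_speed_kmh:
            keep[i] = False
            n_speed += 1
        else:
            anchor = i
        i += 1
    return keep, n_step, n_speed


def filter_speed_distance(fixes: pd.DataFrame,
                          max_speed_kmh: float = MAX_SPEED_KMH,
                          max_step_m: float = MAX_STEP_M_PER_10S
                          ) -> tuple[pd.DataFrame, int, int]:
    """Remove physically impossible jumps, per horse stream.

    Returns ``(retained, n_removed_step, n_removed_speed)``.  Streams must
    be time-sorted within each horse; single-fix streams pass unchanged.
    """
    if len(fixes) == 0:
        return fixes.reset_index(drop=True), 0, 0
    keep_all = np.ones(len(fixes), dtype=bool)
    n_step = n_speed = 0
    t = pd.to_datetime(fixes["timestamp_utc"]).astype("int64").to_numpy() / 1e9
    lat = fixes["lat"].to_numpy()
    lon = fixes["lon"].to_numpy()
    pos = np.arange(len(fixes))
    for _, idx in fixes.groupby("horse_id", sort=False).indices.items():
        k, ns, nv = _scan_stream(lat[idx], lon[idx], t[idx],
                                 max_speed_kmh, max_step_m)
        keep_all[pos[idx]] = k
        n_step += ns
        n_speed += nv
    return fixes.loc[keep_all].reset_index(drop=True), n_step, n_speed


def clip_to_areas(fixes: pd.DataFrame, layout: FarmLayout,
                  include_pasture: bool = True) -> tuple[pd.DataFrame, int]:
    """Keep only fixes inside the paddock (and pasture, if included).

    ``include_pasture=False`` builds the "paddock only" dataset variant:
    pasture fixes are removed along with everything outside the borders.
    Boundary points count as inside.
    """
    if len(fixes) == 0:
        return fixes.reset_index(drop=True), 0
    x, y = project_to_local(fixes["lat"].to_numpy(), fixes["lon"].to_numpy(),
                            layout.projection_origin)
    area = layout.farm_union() if include_pasture else layout.paddock_polygon
    shapely.prepare(area)
    inside = shapely.intersects_xy(area, x, y)
    return fixes.loc[inside].reset_index(drop=True), int((~inside).sum())


def apply_filter_cascade(fixes: pd.DataFrame, layout: FarmLayout,
                         include_pasture: bool = True,
                         max_speed_kmh: float = MAX_SPEED_KMH,
                         max_step_m: float = MAX_STEP_M_PER_10S
                         ) -> tuple[pd.DataFrame, FilterReport]:
    """Full cleaning cascade: bounding box -> speed/step -> area clip.

    Equivalent to composing the three stage functions; masks are composed
    and the frame subset once, so large streams are not copied per stage.
    """
    report = FilterReport(n_input=len(fixes))
    if len(fixes) == 0:
        report.n_retained = 0
        return fixes.reset_index(drop=True), report
    lat = fixes["lat"].to_numpy()
    lon = fixes["lon"].to_numpy()

    lat_min, lat_max, lon_min, lon_max = layout.bounding_box_geodetic()
    inside = (lat >= lat_min) & (lat <= lat_max) & (lon >= lon_min) & (lon <= lon_max)
    report.removed_bbox = int((~inside).sum())
    idx = np.flatnonzero(inside)

    t = pd.to_datetime(fixes["timestamp_utc"]).astype("int64").to_numpy() / 1e9
    horse_codes, _ = pd.factorize(fixes["horse_id"].to_numpy()[idx])
    keep = np.ones(len(idx), dtype=bool)
    for k in range(horse_codes.max() + 1 if len(idx) else 0):
        sub = np.flatnonzero(horse_codes == k)
        km, ns, nv = _scan_stream(lat[idx[sub]], lon[idx[sub]], t[idx[sub]],
                                  max_speed_kmh, max_step_m)
        keep[sub] = km
        report.removed_step += ns
        report.removed_speed += nv
    idx = idx[keep]

    x, y = project_to_local(lat[idx], lon[idx], layout.projection_origin)
    area = layout.farm_union() if include_pasture else layout.paddock_polygon
    shapely.prepare(area)
    in_area = shapely.intersects_xy(area, x, y)
    report.removed_outside_area = int((~in_area).sum())
    idx = idx[in_area]

    report.n_retained = len(idx)
    report.check()
    return fixes.iloc[idx].reset_index(drop=True), report


def flag_demolished_days(day_loss_fraction: pd.Series,
                         limit: float = DEMOLISHED_FRACTION) -> pd.Series:
    """Flag horse-days whose malformed/removed fraction exceeds the limit.

    Operationalises the exclusion of "heavily demolished or incorrectly
    adjusted" loggers: the input maps (horse, day) keys to the fraction of
    that day's rows lost to parse errors plus filter removals; the result
    is a boolean exclusion flag per key.
    """
    return day_loss_fraction > limit
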