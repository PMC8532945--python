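"""Independent brute-force oracles and small fixture builders.

Every oracle here is deliberately written as the dumbest correct
computation (per-point loops, dict tallies, closed-form algebra) and
shares no code path with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

MEAN_EARTH_RADIUS = 6_371_008.8


# ---------------------------------------------------------------------------
# geometry oracles
# ---------------------------------------------------------------------------

def oracle_great_circle_m(lat1, lon1, lat2, lon2):
    """Great-circle distance via the sphere-case Vincenty formula (scalar).

    The atan2 form is numerically stable at farm-scale separations.
    """
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    num = math.hypot(
        math.cos(p2) * math.sin(dl),
        math.cos(p1) * math.sin(p2) - math.sin(p1) * math.cos(p2) * math.cos(dl))
    den = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return MEAN_EARTH_RADIUS * math.atan2(num, den)


def oracle_grid_assign(xs, ys, grid):
    """Assign points to cells by looping over all cells with half-open tests.

    Asserts every point lands in exactly one cell; returns (rows, cols).
    """
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    rows = np.full(len(xs), -1)
    cols = np.full(len(xs), -1)
    hits = np.zeros(len(xs), dtype=int)
    s = grid.cell_size
    for r in range(grid.n_rows):
        y0 = grid.origin_y + r * s
        in_row = (ys >= y0) & (ys < y0 + s)
        if not in_row.any():
            continue
        for c in range(grid.n_cols):
            x0 = grid.origin_x + c * s
            m = in_row & (xs >= x0) & (xs < x0 + s)
            rows[m] = r
            cols[m] = c
            hits[m] += 1
    assert (hits == 1).all(), "oracle: a point fell in != 1 cell"
    return rows, cols


def oracle_point_in_polygon(poly, x, y):
    """Even-odd ray casting against the polygon exterior ring (no holes).

    Intended for points not lying exactly on edges.
    """
    coords = np.asarray(poly.exterior.coords)
    inside = False
    j = len(coords) - 1
    for i in range(len(coords)):
        xi, yi = coords[i]
        xj, yj = coords[j]
        if (yi > y) != (yj > y):
            x_cross = (xj - xi) * (y - yi) / (yj - yi) + xi
            if x < x_cross:
                inside = not inside
        j = i
    return inside


def oracle_in_any_polygon(polys, x, y):
    return any(oracle_point_in_polygon(p, x, y) for p in polys)


# ---------------------------------------------------------------------------
# metric oracles
# ---------------------------------------------------------------------------

def oracle_squares_per_hour(day_fixes, grid, origin, min_per_hour=324):
    """Mean distinct-square count over well-covered clock hours (set loop)."""
    from stablegrid import project_to_local

    hours = {}
    ts = pd.to_datetime(day_fixes["timestamp_local"])
    for (_, fix), t in zip(day_fixes.iterrows(), ts):
        x, y = project_to_local(fix["lat"], fix["lon"], origin)
        r = math.floor((y - grid.origin_y) / grid.cell_size)
        c = math.floor((x - grid.origin_x) / grid.cell_size)
        hours.setdefault(t.hour, []).append((r, c))
    vals = [len(set(v)) for v in hours.values() if len(v) >= min_per_hour]
    return sum(vals) / len(vals) if vals else None


def oracle_square_frequencies(day_fixes, grid, origin):
    """Dict tally of per-square percentages for one day."""
    from stablegrid import project_to_local

    tally: dict[tuple[int, int], int] = {}
    for _, fix in day_fixes.iterrows():
        x, y = project_to_local(fix["lat"], fix["lon"], origin)
        key = (math.floor((y - grid.origin_y) / grid.cell_size),
               math.floor((x - grid.origin_x) / grid.cell_size))
        tally[key] = tally.get(key, 0) + 1
    n = sum(tally.values())
    return {k: 100.0 * v / n for k, v in tally.items()}


# ---------------------------------------------------------------------------
# model oracle
# ---------------------------------------------------------------------------

def oracle_gls(y, X, groups, sigma_a2, sigma_e2):
    """Closed-form GLS fixed effects at given variance components.

    V = sigma_a2 * Z Z' + sigma_e2 * I with Z the per-group indicator.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    Z = (groups[:, None] == levels[None, :]).astype(float)
    V = sigma_a2 * Z @ Z.T + sigma_e2 * np.eye(len(y))
    Vi = np.linalg.inv(V)
    return np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)


# ---------------------------------------------------------------------------
# fixture builders
# ---------------------------------------------------------------------------

def fixes_from_planar(xy, layout, horse_id=1, start="2019-06-01",
                      interval_s=10.0):
    """Build a canonical fix table from planar positions (no noise)."""
    from stablegrid import unproject_from_local
    from stablegrid.farm_geometry import haversine_m

    xy = np.asarray(xy, dtype=float)
    lat, lon = unproject_from_local(xy[:, 0], xy[:, 1],
                                    layout.projection_origin)
    lat = np.atleast_1d(lat)
    lon = np.atleast_1d(lon)
    n = len(lat)
    t_local = pd.Timestamp(start) + pd.to_timedelta(
        np.arange(n) * interval_s, unit="s")
    step = np.zeros(n)
    if n > 1:
        step[1:] = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
    return pd.DataFrame({
        "horse_id": np.int64(horse_id),
        "timestamp_local": t_local,
        "timestamp_utc": t_local - pd.Timedelta(hours=2),
        "lat": lat, "lon": lon, "height_m": 20.0,
        "speed_kmh": step / interval_s * 3.6, "step_distance_m": step,
    })


def recovery_usage_table(seed, n_horses=20, n_days=60, summer_days=40):
    """Simulate a scaled study and push it through cascade + usage metric.

    Processes horse by horse to bound memory; returns (usage table,
    metadata frame, ground-truth animal effects dict).
    """
    import stablegrid as sg

    cfg = sg.SimulationConfig(
        n_horses=n_horses, n_days=n_days, summer_days=summer_days,
        winter_days=n_days - summer_days,
        n_newcomers=max(1, round(12 * n_horses / 52)),
        dropout_prob=0.01, rng_seed=seed)
    layout = sg.default_farm_layout(summer_days=summer_days)
    grid = sg.GridSpec.from_layout(layout)
    metas = sg.make_herd(cfg, seed=seed)
    parts = []
    effects = {}
    for horse in metas:
        res = sg.simulate_study([horse], layout, cfg, seed=seed)
        effects.update(res.animal_effects)
        filt, _ = sg.apply_filter_cascade(res.fixes, layout)
        parts.append(sg.build_usage_table(filt, grid, layout))
    usage = pd.concat(parts, ignore_index=True)
    return usage, sg.metas_frame(metas), effects
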