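"""Agent-based herd simulator producing GPS-logger datasets.

The study's raw farm data are not deposited, so every downstream stage is
exercised on synthetic logger streams with the study's statistical
structure: 52 horses (31 warmblood / 6 pony / 15 other, geldings and
mares, ages 2-29, 12 newcomers entering late), 227 observation days
(159 summer + 68 winter), one fix per 10 s, twice-daily ~90 min pasture
windows in summer, isotropic GPS noise, teleport spikes and dropouts.

Movement follows a semi-Markov behavioural state machine: a horse rests
in a lying hall, feeds at a stall, drinks at a trough, stands at a straw
rack or shelter, loiters on the open paddock, and grazes on the open
pasture during summer windows; it walks between targets by a noisy
direct path.  Age and a per-horse random effect act multiplicatively on
the state-switch rate (shorter dwells = more movement), so their effect
on the squares-per-hour response is emergent, not painted on -- which is
what makes downstream parameter-recovery tests honest.

Ground truth (per-horse effects, the configured age slope, injected
spike fixes) is returned alongside the data for recovery testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .farm_geometry import FarmLayout, unproject_from_local, haversine_m
from .logger_io import FIX_COLUMNS

SECONDS_PER_DAY = 86_400
LOCAL_UTC_OFFSET_H = 2  # fixed local-time offset used for synthetic timestamps
DEFAULT_START_DATE = date(2019, 6, 1)

BREED_CLASSES = ("warmblood", "pony", "other")
SEXES = ("gelding", "mare")

#: behavioural states and where each one anchors
_STATE_ZONES = {
    "rest": ["LH_1", "LH_2", "LH_3"],
    "feed": ["FS_1", "FS_2", "FS_3", "FS_4", "FS_5", "FS_6", "FS_7",
             "CF_1", "CF_2", "CF_3"],
    "drink": ["TR_1", "TR_2"],
    "stand": ["RF_1", "RF_2", "SH_1", "SH_2"],
    "loiter": [],  # anywhere on the open paddock
}


class NoDataError(ValueError):
    """Requested a day before the horse entered the herd."""


@dataclass(frozen=True)
class HorseMeta:
    horse_id: int
    breed_class: str
    sex: str
    age: float           # years, 2-29 in the study herd
    entry_day: int = 1   # 1-based observation-day index of herd entry


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic herd.

    Defaults are the study's stated conditions where the study states
    them (herd size and split, 227 = 159 + 68 days, 10 s cadence, twice
    ~90 min pasture access, age slope -0.6 squares/h per year); the
    remaining movement parameters are realistic free choices documented
    in the methods note.
    """

    n_horses: int = 52
    n_newcomers: int = 12
    n_days: int = 227
    summer_days: int = 159
    winter_days: int = 68
    fix_interval: float = 10.0          # s between fixes
    # semi-Markov behavioural machine
    dwell_means: dict = field(default_factory=lambda: {
        "rest": 2700.0, "feed": 1800.0, "drink": 180.0,
        "stand": 1200.0, "loiter": 900.0,
    })
    state_probs: dict = field(default_factory=lambda: {
        "rest": 0.18, "feed": 0.22, "drink": 0.08,
        "stand": 0.12, "loiter": 0.40,
    })
    walk_speed: float = 1.1             # m/s between targets
    travel_jitter_sd: float = 0.8       # m lateral noise while walking
    dwell_jitter_sd: float = 1.2        # m wander around a dwell anchor
    graze_step: float = 2.5             # m per fix while grazing
    # effect structure (response-scale units: squares/h)
    age_slope: float = -0.6             # squares/h per year of age
    animal_sd: float = 6.0              # SD of the per-horse random effect
    mean_age: float = 12.0              # centering for the age effect
    mobility_scale: float = 25.0        # squares/h units per log switch-rate unit
    # observation process
    gps_noise_sd: float = 2.5           # m isotropic noise per fix
    spike_prob: float = 0.0             # P(fix replaced by a far teleport)
    spike_range: tuple = (200.0, 500.0)  # m teleport offset
    dropout_prob: float = 0.0           # P(fix missing)
    outage_prob: float = 0.0            # P(horse-day loses a contiguous block)
    outage_hours: tuple = (6.0, 20.0)
    # two daily pasture windows (seconds since local midnight), summer only
    pasture_windows: tuple = ((7 * 3600, 7 * 3600 + 5400),
                              (17 * 3600, 17 * 3600 + 5400))
    start_date: date = DEFAULT_START_DATE
    rng_seed: int = 0

    def __post_init__(self):
        if self.summer_days + self.winter_days != self.n_days:
            raise ValueError("summer_days + winter_days must equal n_days")
        for p in (self.spike_prob, self.dropout_prob, self.outage_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def fixes_per_day(self) -> int:
        return int(SECONDS_PER_DAY // self.fix_interval)


def make_herd(cfg: SimulationConfig, seed: int | None = None) -> list[HorseMeta]:
    """Draw herd metadata with the study's composition.

    Breed-class sizes follow the 31/6/15 warmblood/pony/other split
    (scaled proportionally for other herd sizes); ages are uniform on
    2-29 years; newcomers get an entry day after day 1.
    """
    seed = cfg.rng_seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99991,)))
    n = cfg.n_horses
    n_wb = int(round(n * 31 / 52))
    n_po = max(1, int(round(n * 6 / 52))) if n >= 3 else 0
    breeds = (["warmblood"] * n_wb + ["pony"] * n_po
              + ["other"] * (n - n_wb - n_po))
    horses = []
    newcomer_ids = set(rng.choice(n, size=min(cfg.n_newcomers, max(n - 1, 0)),
                                  replace=False) + 1) if cfg.n_newcomers else set()
    for hid in range(1, n + 1):
        entry = 1
        if hid in newcomer_ids and cfg.n_days > 1:
            entry = int(rng.integers(2, cfg.n_days + 1))
        horses.append(HorseMeta(
            horse_id=hid,
            breed_class=breeds[hid - 1],
            sex=SEXES[int(rng.random() < 0.45)],
            age=float(rng.integers(2, 30)),
            entry_day=entry,
        ))
    return horses


def mobility_factor(horse: HorseMeta, animal_effect: float, cfg: SimulationConfig) -> float:
    """Multiplicative state-switch rate for one horse.

    Monotone in ``age_slope * (age - mean_age) + animal_effect``; dwell
    times are divided by this factor, so larger values mean more state
    switches, more travel and more distinct squares per hour.
    """
    eta = cfg.age_slope * (horse.age - cfg.mean_age) + animal_effect
    return math.exp(eta / cfg.mobility_scale)


def _animal_effect(horse_id: int, cfg: SimulationConfig, seed: int) -> float:
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(horse_id,)))
    return float(rng.normal(0.0, cfg.animal_sd))


# ---------------------------------------------------------------------------
# one-day track construction
# ---------------------------------------------------------------------------

def _rect_of(poly, inset: float):
    minx, miny, maxx, maxy = poly.bounds
    return (minx + inset, miny + inset, maxx - inset, maxy - inset)


def _clamp(points: np.ndarray, rect) -> np.ndarray:
    x, y = points[:, 0], points[:, 1]
    np.maximum(x, rect[0], out=x)
    np.minimum(x, rect[2], out=x)
    np.maximum(y, rect[1], out=y)
    np.minimum(y, rect[3], out=y)
    return points


def _reflect(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold a random walk back into [lo, hi] by reflection."""
    span = hi - lo
    w = np.mod(v - lo, 2.0 * span)
    return lo + np.where(w > span, 2.0 * span - w, w)


def _random_point(rect, rng) -> np.ndarray:
    return np.array([rng.uniform(rect[0], rect[2]), rng.uniform(rect[1], rect[3])])


def _gate_point(paddock_poly, pasture_poly) -> np.ndarray:
    """Crossing point between paddock and an adjoining pasture."""
    seam = paddock_poly.boundary.intersection(pasture_poly.boundary)
    if not seam.is_empty:
        p = seam.centroid
        return np.array([p.x, p.y])
    from shapely.ops import nearest_points
    a, b = nearest_points(paddock_poly, pasture_poly)
    return np.array([(a.x + b.x) / 2.0, (a.y + b.y) / 2.0])


class _TrackBuilder:
    def __init__(self, n_fixes, dt, rng, cfg):
        self.pos = np.empty((n_fixes, 2))
        self.n = n_fixes
        self.i = 0
        self.dt = dt
        self.rng = rng
        self.cfg = cfg

    @property
    def full(self):
        return self.i >= self.n

    def travel(self, cur, target, rect):
        """Walk cur -> target at walking speed with lateral jitter."""
        dist = float(np.hypot(*(target - cur)))
        n_steps = max(1, int(math.ceil(dist / (self.cfg.walk_speed * self.dt))))
        n_steps = min(n_steps, self.n - self.i)
        if n_steps <= 0:
            return cur
        frac = np.arange(1, n_steps + 1)[:, None] / n_steps
        pts = cur + (target - cur) * frac
        pts = pts + self.rng.normal(0.0, self.cfg.travel_jitter_sd, pts.shape)
        pts[-1] = target  # arrive exactly
        _clamp(pts, rect)
        self.pos[self.i:self.i + n_steps] = pts
        self.i += n_steps
        return pts[-1].copy()

    def dwell(self, anchor, rect, n_steps):
        n_steps = min(n_steps, self.n - self.i)
        if n_steps <= 0:
            return anchor
        pts = anchor + self.rng.normal(0.0, self.cfg.dwell_jitter_sd, (n_steps, 2))
        _clamp(pts, rect)
        self.pos[self.i:self.i + n_steps] = pts
        self.i += n_steps
        return pts[-1].copy()

    def graze(self, start, rect, n_steps):
        """Correlated random walk across the pasture."""
        n_steps = min(n_steps, self.n - self.i)
        if n_steps <= 0:
            return start
        heading = self.rng.uniform(0, 2 * math.pi) + np.cumsum(
            self.rng.normal(0.0, 0.35, n_steps))
        steps = self.cfg.graze_step * (1.0 + self.rng.normal(0.0, 0.2, n_steps))
        xy = start + np.column_stack([
            np.cumsum(steps * np.cos(heading)),
            np.cumsum(steps * np.sin(heading)),
        ])
        xy[:, 0] = _reflect(xy[:, 0], rect[0], rect[2])
        xy[:, 1] = _reflect(xy[:, 1], rect[1], rect[3])
        self.pos[self.i:self.i + n_steps] = xy
        self.i += n_steps
        return xy[-1].copy()


def _simulate_true_track(horse, day, layout, cfg, rng, animal_effect):
    """True (noise-free) planar positions at every fix time of one day."""
    n_fixes = cfg.fixes_per_day
    dt = cfg.fix_interval
    m = mobility_factor(horse, animal_effect, cfg)
    summer = day <= cfg.summer_days

    paddock_rect = _rect_of(layout.paddock_polygon, 0.5)
    open_pa = layout.open_pastures(day) if summer else []
    pasture = open_pa[0] if open_pa else None
    if pasture is not None:
        pasture_rect = _rect_of(pasture.polygon, 1.0)
        gate = _gate_point(layout.paddock_polygon, pasture.polygon)
        gate_in = np.clip(gate, paddock_rect[:2], paddock_rect[2:])
    zone_rects = {z: _rect_of(p, 0.3) for z, p in layout.resource_zones.items()}

    states = list(cfg.state_probs)
    probs = np.array([cfg.state_probs[s] for s in states])
    cum_probs = np.cumsum(probs / probs.sum())

    tb = _TrackBuilder(n_fixes, dt, rng, cfg)
    cur = _random_point(paddock_rect, rng)
    windows = list(cfg.pasture_windows) if (summer and pasture is not None) else []
    grazed = [False] * len(windows)

    while not tb.full:
        t = tb.i * dt
        win = next((w for w, (a, b) in enumerate(windows)
                    if a <= t < b and not grazed[w]), None)
        if win is not None:
            grazed[win] = True
            end_idx = min(int(windows[win][1] // dt), n_fixes)
            cur = tb.travel(cur, gate_in, paddock_rect)
            start = _random_point(pasture_rect, rng)
            cur = tb.travel(cur, start, pasture_rect)
            cur = tb.graze(cur, pasture_rect, end_idx - tb.i)
            cur = tb.travel(cur, gate_in, pasture_rect)
            cur[0] = gate_in[0]  # back through the gate
            continue
        state = states[int(np.searchsorted(cum_probs, rng.random()))]
        if state == "loiter" or not _STATE_ZONES[state]:
            rect = paddock_rect
            anchor = _random_point(paddock_rect, rng)
        else:
            zone = _STATE_ZONES[state][rng.integers(len(_STATE_ZONES[state]))]
            rect = zone_rects[zone]
            anchor = _random_point(rect, rng)
        mean_dwell = cfg.dwell_means[state] / m
        duration = float(np.clip(rng.exponential(mean_dwell), 60.0, 4.0 * mean_dwell))
        # stop a dwell at the next pasture window so grazing is not skipped
        nxt = min((a for w, (a, b) in enumerate(windows)
                   if not grazed[w] and a >= t), default=None)
        if nxt is not None:
            duration = min(duration, max(nxt - t, 60.0))
        cur = tb.travel(cur, anchor, paddock_rect)
        cur = tb.dwell(anchor, rect, int(round(duration / dt)))
    return tb.pos


def simulate_day(horse: HorseMeta, day: int, layout: FarmLayout,
                 cfg: SimulationConfig, seed: int | None = None,
                 animal_effect: float | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one horse-day of logger fixes.

    Returns ``(fixes, spikes)``: the emitted fix table (canonical columns,
    dropouts removed) and the ground-truth spike rows that survived
    dropout.  Raises :class:`NoDataError` before the horse's entry day.
    Reproducible: the random stream is keyed by ``(seed, horse_id, day)``
    so any subset of horses or days replays identically.
    """
    if day < horse.entry_day:
        raise NoDataError(f"horse {horse.horse_id} entered on day {horse.entry_day}")
    seed = cfg.rng_seed if seed is None else seed
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(horse.horse_id, day)))
    if animal_effect is None:
        animal_effect = _animal_effect(horse.horse_id, cfg, seed)

    true_xy = _simulate_true_track(horse, day, layout, cfg, rng, animal_effect)
    n = len(true_xy)

    obs = true_xy + rng.normal(0.0, cfg.gps_noise_sd, (n, 2))
    spike_mask = rng.random(n) < cfg.spike_prob
    if spike_mask.any():
        k = int(spike_mask.sum())
        r = rng.uniform(*cfg.spike_range, k)
        th = rng.uniform(0, 2 * math.pi, k)
        obs[spike_mask] = true_xy[spike_mask] + np.column_stack(
            [r * np.cos(th), r * np.sin(th)])

    keep = rng.random(n) >= cfg.dropout_prob
    if cfg.outage_prob > 0 and rng.random() < cfg.outage_prob:
        hours = rng.uniform(*cfg.outage_hours)
        n_out = int(hours * 3600 / cfg.fix_interval)
        start = int(rng.integers(0, max(n - n_out, 1)))
        keep[start:start + n_out] = False

    lat, lon = unproject_from_local(obs[:, 0], obs[:, 1], layout.projection_origin)
    local0 = pd.Timestamp(cfg.start_date + timedelta(days=day - 1))
    t_local = pd.DatetimeIndex(
        local0.value + (np.arange(n) * (cfg.fix_interval * 1e9)).astype("int64"))
    fixes = pd.DataFrame({
        "horse_id": np.int64(horse.horse_id),
        "timestamp_local": t_local,
        "timestamp_utc": t_local - pd.Timedelta(hours=LOCAL_UTC_OFFSET_H),
        "lat": lat,
        "lon": lon,
        "height_m": 20.0 + rng.normal(0.0, 1.0, n),
    })
    step = np.zeros(n)
    step[1:] = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
    fixes["speed_kmh"] = step / cfg.fix_interval * 3.6
    fixes["step_distance_m"] = step

    fixes = fixes.loc[keep].reset_index(drop=True)
    spikes = fixes.loc[spike_mask[keep], ["horse_id", "timestamp_utc"]].copy()
    spikes["day"] = day
    return fixes[FIX_COLUMNS], spikes.reset_index(drop=True)


@dataclass
class SimulationResult:
    """Logger dataset plus the ground truth that generated it."""

    fixes: pd.DataFrame
    animal_effects: dict[int, float]
    spikes: pd.DataFrame            # horse_id, timestamp_utc, day
    age_slope: float
    mean_age: float
    seed: int


def simulate_study(metas: list[HorseMeta], layout: FarmLayout,
                   cfg: SimulationConfig, seed: int | None = None,
                   days: list[int] | None = None) -> SimulationResult:
    """Simulate the whole study (every horse, every post-entry day)."""
    if not metas:
        raise ValueError("metas must be nonempty")
    seed = cfg.rng_seed if seed is None else seed
    effects = {h.horse_id: _animal_effect(h.horse_id, cfg, seed) for h in metas}
    day_list = days if days is not None else range(1, cfg.n_days + 1)
    fix_parts, spike_parts = [], []
    for horse in metas:
        for day in day_list:
            if day < horse.entry_day:
                continue
            f, s = simulate_day(horse, day, layout, cfg, seed=seed,
                                animal_effect=effects[horse.horse_id])
            fix_parts.append(f)
            if len(s):
                spike_parts.append(s)
    fixes = pd.concat(fix_parts, ignore_index=True)
    spikes = (pd.concat(spike_parts, ignore_index=True) if spike_parts
              else pd.DataFrame(columns=["horse_id", "timestamp_utc", "day"]))
    return SimulationResult(fixes=fixes, animal_effects=effects, spikes=spikes,
                            age_slope=cfg.age_slope, mean_age=cfg.mean_age,
                            seed=seed)


def metas_frame(metas: list[HorseMeta]) -> pd.DataFrame:
    """Animal metadata as a tidy table (one row per horse)."""
    return pd.DataFrame([{
        "horse_id": h.horse_id, "breed_class": h.breed_class, "sex": h.sex,
        "age": h.age, "entry_day": h.entry_day,
    } for h in metas])
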