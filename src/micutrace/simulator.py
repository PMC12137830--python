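"""Agent-based MICU badge simulator.

Generates synthetic raw badge data in the exact published record format,
together with ground-truth contact episodes, so the whole processing chain
can be exercised and validated without the deposited dataset.

The simulator has three layers:

* **layout** -- patient rooms along a central corridor, four anchors per room
  (door, sink, computer workstation, vitals monitor), with every pair of
  anchors more than six feet apart;
* **movement** -- healthcare professionals as agents alternating dwell
  episodes at stations (assigned rooms for nurses, rounds for providers,
  sporadic visits for support staff) with corridor walks between them; the
  deployment's handout/turn-in protocol is reproduced, including badges
  stacked together in a receptacle around shift boundaries and powered-on
  unworn badges that disappear within half an hour of shift start;
* **sensing** -- a UWB badge model: every ``low_cycle_s`` seconds each badge
  ranges its neighbors (six-foot contact threshold, Gaussian distance noise
  of about ten centimeters), and every ``high_cycle_s`` (15 s) a higher-level
  processing cycle opens and purges contact intervals.  Matched start/end
  record pairs therefore carry durations quantized to multiples of 15 s,
  contacts shorter than one processing cycle leave a lone start record, and
  per-badge clock offsets desynchronize the reported times.

All randomness flows from ``SimScenario.seed`` through
``numpy.random.default_rng``; identical scenario and seed give an identical
record stream.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .records import (
    AnchorPlacement,
    BadgeId,
    RawRecord,
    Role,
    ShiftSpec,
    Station,
)

logger = logging.getLogger("micutrace")

__all__ = [
    "SimScenario",
    "TrueContact",
    "Layout",
    "Trajectories",
    "ShiftResult",
    "generate_layout",
    "simulate_movement",
    "scripted_trajectories",
    "true_contacts",
    "sense_and_emit",
    "simulate_shift",
    "simulate",
    "to_utc_export",
]

# ---- geometry constants (feet) -------------------------------------------

ROOM_W = 20.0          # room width along the corridor
ROOM_D = 20.0          # room depth
CORRIDOR_W = 10.0      # corridor width between the two room rows
WALK_SPEED_FT_S = 4.0  # agent walking speed

#: acquisition-time UTC offset of the deployment site (UTC-5)
UTC_OFFSET_H = 5


@dataclass(frozen=True)
class RosterCounts:
    """Per-role HCP head counts for one shift kind."""

    provider: int
    nurse: int
    support: int

    def __post_init__(self) -> None:
        if min(self.provider, self.nurse, self.support) < 0:
            raise ValueError("roster counts must be nonnegative")

    def total(self) -> int:
        return self.provider + self.nurse + self.support


@dataclass
class SimScenario:
    """Simulator configuration.

    Defaults reproduce the deployment: a 26-room single-occupancy MICU with
    four anchors per room, a six-foot (72 in) contact threshold sensed with
    roughly ten-centimeter (4 in) accuracy, a few-second low-level signaling
    cycle under a 15-second processing cycle, day rosters of 12 providers /
    19 nurses / 12 support staff against 6/15/8 at night, and fourteen
    working 12-hour shifts (indices 1-14; even = day, odd = night).
    """

    seed: int = 0
    rooms: int = 26
    day_roster: RosterCounts = field(default_factory=lambda: RosterCounts(12, 19, 12))
    night_roster: RosterCounts = field(default_factory=lambda: RosterCounts(6, 15, 8))
    shift_indices: tuple[int, ...] = tuple(range(1, 15))
    first_day: _dt.date = _dt.date(2023, 4, 21)
    contact_threshold_in: int = 72
    distance_noise_in: float = 4.0
    low_cycle_s: int = 3
    high_cycle_s: int = 15
    clock_drift_s: int = 5
    receptacle_artifacts: bool = True
    extra_badges: int = 2
    pixels_per_foot: float = 4.0

    def __post_init__(self) -> None:
        if self.high_cycle_s % self.low_cycle_s:
            raise ValueError("high_cycle_s must be a multiple of low_cycle_s")
        if self.contact_threshold_in <= 0:
            raise ValueError("contact threshold must be positive")
        if self.distance_noise_in < 0:
            raise ValueError("distance noise must be nonnegative")
        if self.clock_drift_s < 0:
            raise ValueError("clock drift range must be nonnegative")

    def roster(self, shift: ShiftSpec) -> RosterCounts:
        return self.day_roster if shift.kind == "day" else self.night_roster

    def shift_plan(self) -> list[ShiftSpec]:
        return [ShiftSpec.from_index(i, self.first_day) for i in self.shift_indices]


@dataclass(frozen=True)
class TrueContact:
    """Ground truth: a maximal episode of two badges within the threshold."""

    badge_a: BadgeId
    badge_b: BadgeId
    true_start: _dt.datetime
    true_end: _dt.datetime
    min_distance_in: float

    def __post_init__(self) -> None:
        if self.true_end <= self.true_start:
            raise ValueError("true_end must follow true_start")

    @property
    def duration_s(self) -> int:
        return int((self.true_end - self.true_start).total_seconds())


# --------------------------------------------------------------------------
# Layout
# --------------------------------------------------------------------------

@dataclass
class Layout:
    """Generated MICU geometry: anchors, their feet-space positions, and
    the movement waypoints agents use."""

    n_rooms: int
    pixels_per_foot: float
    placements: list[AnchorPlacement]                 # pixel coordinates
    anchor_pos_ft: dict[BadgeId, tuple[float, float]]
    station_pos_ft: dict[tuple[int, Station], tuple[float, float]]
    room_row: dict[int, str]                          # room -> "top" | "bottom"
    handout_ft: tuple[float, float]
    nurse_stations_ft: list[tuple[float, float]]
    corridor_y_ft: float


def _room_stations(room: int, col: int, row: str) -> dict[Station, tuple[float, float]]:
    x0 = col * ROOM_W
    if row == "top":
        return {
            Station.DOOR: (x0 + 10.0, 19.0),
            Station.SINK: (x0 + 4.0, 4.0),
            Station.COMPUTER: (x0 + 16.0, 4.0),
            Station.VITALS: (x0 + 10.0, 10.0),
        }
    return {
        Station.DOOR: (x0 + 10.0, 31.0),
        Station.SINK: (x0 + 4.0, 46.0),
        Station.COMPUTER: (x0 + 16.0, 46.0),
        Station.VITALS: (x0 + 10.0, 40.0),
    }


def generate_layout(scenario: SimScenario) -> Layout:
    """Place ``scenario.rooms`` patient rooms in two rows along a corridor.

    Each room carries one anchor at each of the four station types; the
    construction guarantees pairwise anchor separation above six feet both
    within and across rooms.  Deterministic: the geometry depends only on
    the room count.
    """
    n = scenario.rooms
    if n < 1:
        raise ValueError("a layout needs at least one patient room")

    placements: list[AnchorPlacement] = []
    anchor_pos: dict[BadgeId, tuple[float, float]] = {}
    station_pos: dict[tuple[int, Station], tuple[float, float]] = {}
    room_row: dict[int, str] = {}
    top_n = (n + 1) // 2
    order = (Station.DOOR, Station.SINK, Station.COMPUTER, Station.VITALS)
    k = 1
    for room in range(1, n + 1):
        row = "top" if room <= top_n else "bottom"
        col = (room - 1) if row == "top" else (room - top_n - 1)
        room_row[room] = row
        for station in order:
            x, y = _room_stations(room, col, row)[station]
            anchor = BadgeId.make(Role.ANCHOR, k)
            k += 1
            anchor_pos[anchor] = (x, y)
            station_pos[(room, station)] = (x, y)
            placements.append(AnchorPlacement(
                anchor=anchor, room=room, station=station,
                x=round(x * scenario.pixels_per_foot, 1),
                y=round(y * scenario.pixels_per_foot, 1),
            ))

    length = top_n * ROOM_W
    corridor_y = ROOM_D + CORRIDOR_W / 2.0
    n_ns = max(1, min(3, n // 8))
    nurse_stations = [
        ((j + 1) * length / (n_ns + 1), corridor_y) for j in range(n_ns)
    ]
    layout = Layout(
        n_rooms=n,
        pixels_per_foot=scenario.pixels_per_foot,
        placements=placements,
        anchor_pos_ft=anchor_pos,
        station_pos_ft=station_pos,
        room_row=room_row,
        handout_ft=(-12.0, corridor_y),
        nurse_stations_ft=nurse_stations,
        corridor_y_ft=corridor_y,
    )
    _check_separation(layout, scenario.contact_threshold_in)
    return layout


def _check_separation(layout: Layout, threshold_in: float) -> None:
    pos = np.array(list(layout.anchor_pos_ft.values()))
    if len(pos) < 2:
        return
    d = np.hypot(pos[:, None, 0] - pos[None, :, 0], pos[:, None, 1] - pos[None, :, 1])
    np.fill_diagonal(d, np.inf)
    min_ft = float(d.min())
    if min_ft * 12.0 <= threshold_in:
        raise ValueError(
            f"anchor separation {min_ft:.1f} ft violates the contact threshold; "
            "request a larger layout"
        )


# --------------------------------------------------------------------------
# Badge rosters
# --------------------------------------------------------------------------

#: overprovisioned badge pool sizes per role (badges are reused across
#: shifts but never within one)
_POOL = {Role.PROVIDER: 20, Role.NURSE: 30, Role.SUPPORT: 20}


def _shift_badges(scenario: SimScenario, shift: ShiftSpec,
                  rng: np.random.Generator) -> tuple[list[BadgeId], list[BadgeId]]:
    """Randomly draw worn badges from the per-role pools, plus powered-on
    unworn extras; returns (worn, extra)."""
    roster = scenario.roster(shift)
    worn: list[BadgeId] = []
    taken: dict[Role, np.ndarray] = {}
    for role, count in ((Role.PROVIDER, roster.provider),
                        (Role.NURSE, roster.nurse),
                        (Role.SUPPORT, roster.support)):
        pool = _POOL[role]
        need = count + (scenario.extra_badges if role is Role.NURSE else 0)
        if need > pool:
            raise ValueError(f"{role.value} roster exceeds the badge pool ({pool})")
        picks = rng.choice(pool, size=need, replace=False) + 1
        taken[role] = picks
        worn.extend(BadgeId.make(role, int(p)) for p in picks[:count])
    extras = [BadgeId.make(Role.NURSE, int(p))
              for p in taken[Role.NURSE][roster.nurse:]]
    return worn, extras


# --------------------------------------------------------------------------
# Movement
# --------------------------------------------------------------------------

@dataclass
class Trajectories:
    """Per-second positions of every badge during one shift.

    ``pos[t, i]`` is badge ``i``'s position in feet at ``shift.start + t``;
    ``active[t, i]`` marks whether the badge is powered on.  Anchors are
    ordinary (stationary, always-on) badges here, so the sensing model treats
    every badge uniformly.
    """

    shift: ShiftSpec
    badges: list[BadgeId]
    pos: np.ndarray       # (T, N, 2) float32, feet
    active: np.ndarray    # (T, N) bool

    @property
    def n_seconds(self) -> int:
        return self.pos.shape[0]

    def index_of(self, badge: BadgeId) -> int:
        return self.badges.index(badge)


# role-specific destination mixes and mean dwell times (seconds); the model
# is semi-Markov: pick a destination, walk there, dwell, repeat
_ROLE_PARAMS = {
    Role.NURSE: dict(p_assigned=0.62, p_station=0.25, p_other=0.08, p_corridor=0.05,
                     dwell_room=260.0, dwell_station=170.0, dwell_corridor=50.0),
    Role.PROVIDER: dict(p_assigned=0.0, p_station=0.30, p_other=0.58, p_corridor=0.12,
                        dwell_room=150.0, dwell_station=200.0, dwell_corridor=50.0),
    Role.SUPPORT: dict(p_assigned=0.0, p_station=0.22, p_other=0.42, p_corridor=0.36,
                       dwell_room=120.0, dwell_station=140.0, dwell_corridor=70.0),
}

_INTERIOR = (Station.SINK, Station.COMPUTER, Station.VITALS)
_INTERIOR_P = (0.25, 0.35, 0.40)


def _dwell_point(layout: Layout, room: int, station: Station,
                 rng: np.random.Generator) -> tuple[float, float]:
    """Where an agent stands while using a station: a couple of feet to the
    side of the anchor (a worn badge is never on top of a wall-mounted one),
    plus up to a foot of jitter."""
    x, y = layout.station_pos_ft[(room, station)]
    jx, jy = rng.uniform(-1.0, 1.0, size=2)
    return (x + 2.0 + jx, y + jy)


def _walk_path(p: tuple[float, float], q: tuple[float, float],
               lane_y: float) -> list[tuple[float, float]]:
    """Rectilinear path between two points via the corridor lane."""
    path = [p]
    if abs(p[1] - lane_y) > 0.5:
        path.append((p[0], lane_y))
    if abs(q[0] - p[0]) > 0.5:
        path.append((q[0], lane_y))
    path.append(q)
    return path


def _fill_walk(pos: np.ndarray, t: int, path: list[tuple[float, float]],
               speed: float) -> int:
    """Fill per-second positions along a polyline; returns the arrival time."""
    pts = np.asarray(path, dtype=np.float64)
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = float(seg_len.sum())
    n_steps = max(1, int(math.ceil(total / speed)))
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    T = pos.shape[0]
    for s in range(n_steps):
        if t + s >= T:
            return T
        dist = total * (s + 1) / n_steps
        j = int(np.searchsorted(cum, dist, side="right")) - 1
        j = min(j, len(seg) - 1)
        frac = 0.0 if seg_len[j] == 0 else (dist - cum[j]) / seg_len[j]
        pos[t + s] = pts[j] + frac * seg[j]
    return min(t + n_steps, T)


def simulate_movement(scenario: SimScenario, layout: Layout, shift: ShiftSpec,
                      rng: np.random.Generator | None = None) -> Trajectories:
    """Simulate one shift of HCP movement; returns per-second trajectories.

    Agents pick up badges at the handout point within the first ten minutes
    (before pickup the badge sits in the handout receptacle, stacked inches
    from its neighbors when ``receptacle_artifacts`` is on), move from
    station to station per their role's semi-Markov mobility mix, and return
    the badge to the receptacle in the last minutes of the shift.  Unworn
    extra badges stay in the receptacle and power off within half an hour.
    """
    if rng is None:
        rng = np.random.default_rng([scenario.seed, shift.index])

    worn, extras = _shift_badges(scenario, shift, rng)
    anchors = list(layout.anchor_pos_ft)
    badges = worn + extras + anchors
    T = shift.duration_s
    N = len(badges)
    pos = np.zeros((T, N, 2), dtype=np.float32)
    active = np.ones((T, N), dtype=bool)

    hx, hy = layout.handout_ft
    spread = 0.35 if scenario.receptacle_artifacts else 4.0

    def receptacle_spot(i: int) -> tuple[float, float]:
        ang = 2.0 * math.pi * (i % 16) / 16.0
        r = spread * (0.3 + 0.7 * ((i * 7) % 5) / 4.0)
        return (hx + r * math.cos(ang), hy + r * math.sin(ang))

    # stationary anchors
    for j, a in enumerate(anchors):
        pos[:, len(worn) + len(extras) + j] = layout.anchor_pos_ft[a]

    # powered-on unworn badges: receptacle until power-off
    for j in range(len(extras)):
        i = len(worn) + j
        pos[:, i] = receptacle_spot(i)
        off_t = int(rng.integers(300, 1800))  # within half an hour
        active[off_t:, i] = False

    rooms = list(range(1, layout.n_rooms + 1))
    nurse_ids = [i for i, b in enumerate(worn) if b.role is Role.NURSE]
    assigned: dict[int, list[int]] = {}
    for idx, i in enumerate(nurse_ids):
        base = rooms[idx % len(rooms)]
        second = rooms[(idx + len(nurse_ids)) % len(rooms)]
        assigned[i] = [base] if base == second else [base, second]

    for i, badge in enumerate(worn):
        params = _ROLE_PARAMS[badge.role]
        pickup = int(rng.integers(0, 600))
        turn_in = T - int(rng.integers(60, 300))
        spot = receptacle_spot(i)
        pos[:pickup, i] = spot
        t = pickup
        cur = (hx, hy + rng.uniform(-2, 2))
        if t < T:
            pos[t, i] = cur
        t += 1
        while t < turn_in:
            u = rng.random()
            if u < params["p_assigned"] and assigned.get(i):
                room = int(rng.choice(assigned[i]))
                station = Station(rng.choice([s.value for s in _INTERIOR], p=_INTERIOR_P))
                dest = _dwell_point(layout, room, station, rng)
                mean = params["dwell_room"]
            elif u < params["p_assigned"] + params["p_other"]:
                room = int(rng.choice(rooms))
                station = Station(rng.choice([s.value for s in _INTERIOR], p=_INTERIOR_P))
                dest = _dwell_point(layout, room, station, rng)
                mean = params["dwell_room"]
            elif u < params["p_assigned"] + params["p_other"] + params["p_station"]:
                sx, sy = layout.nurse_stations_ft[
                    int(rng.integers(len(layout.nurse_stations_ft)))]
                dest = (sx + rng.uniform(-2.5, 2.5), sy + rng.uniform(-1.5, 1.5))
                mean = params["dwell_station"]
            else:
                length = ((layout.n_rooms + 1) // 2) * ROOM_W
                dest = (rng.uniform(0, length), layout.corridor_y_ft + rng.uniform(-2, 2))
                mean = params["dwell_corridor"]

            lane = layout.corridor_y_ft + rng.uniform(-1.5, 1.5)
            t = _fill_walk(pos[:, i], t, _walk_path(cur, dest, lane), WALK_SPEED_FT_S)
            cur = dest
            dwell = int(np.clip(rng.gamma(2.0, mean / 2.0), 30, 1500))
            end = min(t + dwell, turn_in)
            pos[t:end, i] = cur
            t = end
        # turn-in: walk back and drop the badge in the receptacle
        lane = layout.corridor_y_ft
        t = _fill_walk(pos[:, i], t, _walk_path(cur, spot, lane), WALK_SPEED_FT_S)
        pos[t:, i] = spot

    return Trajectories(shift=shift, badges=badges, pos=pos, active=active)


def scripted_trajectories(
    shift: ShiftSpec,
    plans: dict[BadgeId, list[tuple[int, int, tuple[float, float]]]],
    layout: Layout | None = None,
    walk_speed: float = WALK_SPEED_FT_S,
    horizon_s: int | None = None,
) -> Trajectories:
    """Build trajectories from explicit dwell plans, for recovery testing.

    ``plans`` maps each badge to dwell segments ``(t0, t1, (x, y))`` in
    seconds from shift start; between segments the badge walks in a straight
    line at ``walk_speed``.  Before its first and after its last segment the
    badge holds that segment's position.  Anchors of ``layout`` are appended
    as stationary badges.  ``horizon_s`` truncates the simulated window
    below the full shift length.
    """
    badges = list(plans)
    anchor_list = list(layout.anchor_pos_ft) if layout else []
    T = horizon_s if horizon_s is not None else shift.duration_s
    N = len(badges) + len(anchor_list)
    pos = np.zeros((T, N, 2), dtype=np.float32)
    active = np.ones((T, N), dtype=bool)
    for j, a in enumerate(anchor_list):
        pos[:, len(badges) + j] = layout.anchor_pos_ft[a]
    for i, badge in enumerate(badges):
        segs = sorted(plans[badge])
        if not segs:
            raise ValueError(f"{badge}: empty plan")
        pos[: segs[0][0], i] = segs[0][2]
        for k, (t0, t1, p) in enumerate(segs):
            pos[t0:t1, i] = p
            if k + 1 < len(segs):
                nt0, _, q = segs[k + 1]
                t = _fill_walk(pos[:, i], t1, [p, q], walk_speed)
                pos[t:nt0, i] = q
            else:
                pos[t1:, i] = p
    return Trajectories(shift=shift, badges=badges + anchor_list, pos=pos,
                        active=active)


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------

def true_contacts(traj: Trajectories, threshold_in: float,
                  min_duration_s: int = 1) -> list[TrueContact]:
    """Maximal episodes of two badges within ``threshold_in`` inches.

    Computed on the true (noise-free, global-clock) per-second positions;
    anchor-anchor pairs are skipped (anchors never move and are placed more
    than the threshold apart).
    """
    T, N, _ = traj.pos.shape
    thr_ft = threshold_in / 12.0
    is_anchor = np.array([b.is_anchor for b in traj.badges])
    skip = is_anchor[:, None] & is_anchor[None, :]
    open_start = np.full((N, N), -1, dtype=np.int64)
    min_d = np.full((N, N), np.inf)
    iu = np.triu(np.ones((N, N), dtype=bool), k=1) & ~skip
    out: list[TrueContact] = []
    epoch = traj.shift.start

    def close(i: int, j: int, t_end: int) -> None:
        out.append(TrueContact(
            badge_a=traj.badges[i], badge_b=traj.badges[j],
            true_start=epoch + _dt.timedelta(seconds=int(open_start[i, j])),
            true_end=epoch + _dt.timedelta(seconds=int(t_end)),
            min_distance_in=float(min_d[i, j]) * 12.0,
        ))
        open_start[i, j] = -1
        min_d[i, j] = np.inf

    for t in range(T):
        p = traj.pos[t].astype(np.float64)
        d = np.hypot(p[:, None, 0] - p[None, :, 0], p[:, None, 1] - p[None, :, 1])
        act = traj.active[t]
        under = (d <= thr_ft) & iu & act[:, None] & act[None, :]
        was_open = open_start >= 0
        closing = was_open & ~under
        for i, j in np.argwhere(closing):
            close(i, j, t)
        newly = under & ~was_open
        open_start[newly] = t
        np.minimum(min_d, np.where(under, d, np.inf), out=min_d)
    for i, j in np.argwhere(open_start >= 0):
        close(i, j, T)

    out = [c for c in out if c.duration_s >= min_duration_s]
    out.sort(key=lambda c: (c.true_start, c.badge_a, c.badge_b))
    return out


# --------------------------------------------------------------------------
# Sensing
# --------------------------------------------------------------------------

def sense_and_emit(traj: Trajectories, scenario: SimScenario,
                   rng: np.random.Generator | None = None) -> list[RawRecord]:
    """Run the badge sensing model over trajectories; emit raw records.

    Every ``low_cycle_s`` each badge ranges every other active badge
    (distance plus truncated-Gaussian noise).  At every ``high_cycle_s``
    boundary the badge's processor reconciles its contact list:

    * a pair first sensed under the threshold opens a contact; the start
      record carries the first under-threshold sample's time and sensed
      distance;
    * a full processing cycle with no under-threshold sample purges the
      contact; if the contact's sample support spanned at least one full
      cycle, an end record is written whose duration is the span rounded to
      the nearest multiple of ``high_cycle_s`` -- otherwise the contact is
      ignored as too brief and only the lone start record remains;
    * contacts still open at shift end are purged the same way (badges are
      scanned at turn-in).

    Each badge's reported times are shifted by its constant clock offset
    (uniform integer in ±``clock_drift_s``); the ground truth stays on the
    global clock.  Contacts shorter than ``low_cycle_s`` can fall between
    samples and be missed entirely.
    """
    if rng is None:
        rng = np.random.default_rng([scenario.seed, traj.shift.index, 1])

    T, N, _ = traj.pos.shape
    low, high = scenario.low_cycle_s, scenario.high_cycle_s
    thr_ft = scenario.contact_threshold_in / 12.0
    noise_ft = scenario.distance_noise_in / 12.0
    per_win = high // low

    offsets = rng.integers(-scenario.clock_drift_s, scenario.clock_drift_s + 1,
                           size=N)

    # open-contact state per directed pair (reporter, detected)
    open_first = np.full((N, N), -1, dtype=np.int64)
    open_last = np.zeros((N, N), dtype=np.int64)
    open_dist = np.zeros((N, N), dtype=np.float32)   # sensed feet at recognition

    # state accumulated within the current high-level window
    win_hit = np.zeros((N, N), dtype=bool)
    win_first = np.zeros((N, N), dtype=np.int64)
    win_last = np.zeros((N, N), dtype=np.int64)
    win_dist = np.zeros((N, N), dtype=np.float32)

    eye = np.eye(N, dtype=bool)
    records: list[RawRecord] = []
    epoch = traj.shift.start

    def emit(i: int, j: int) -> None:
        first = int(open_first[i, j])
        span = int(open_last[i, j]) - first
        start = epoch + _dt.timedelta(seconds=first + int(offsets[i]))
        dist_in = max(0, int(round(float(open_dist[i, j]) * 12.0)))
        records.append(RawRecord(traj.badges[i], traj.badges[j], start,
                                 dist_in, 0))
        if span >= high:
            duration = int(high * round(span / high))
            records.append(RawRecord(traj.badges[i], traj.badges[j], start,
                                     dist_in, duration))
        open_first[i, j] = -1

    def process_window() -> None:
        was_open = open_first >= 0
        purge = was_open & ~win_hit
        for i, j in np.argwhere(purge):
            emit(i, j)
        cont = was_open & win_hit
        open_last[cont] = win_last[cont]
        newly = win_hit & ~was_open
        open_first[newly] = win_first[newly]
        open_last[newly] = win_last[newly]
        open_dist[newly] = win_dist[newly]
        win_hit[:] = False

    sample_times = range(0, T, low)
    samples_seen = 0
    for t in sample_times:
        p = traj.pos[t].astype(np.float64)
        d = np.hypot(p[:, None, 0] - p[None, :, 0], p[:, None, 1] - p[None, :, 1])
        if noise_ft > 0:
            d = np.maximum(d + rng.standard_normal((N, N)) * noise_ft, 0.0)
        act = traj.active[t]
        under = (d <= thr_ft) & ~eye & act[:, None] & act[None, :]
        newly = under & ~win_hit
        win_first[newly] = t
        win_dist[newly] = d[newly]
        win_last[under] = t
        win_hit |= under
        samples_seen += 1
        if samples_seen % per_win == 0:
            process_window()
    if samples_seen % per_win:
        process_window()
    # shift end: badges scanned, remaining contacts purged
    for i, j in np.argwhere(open_first >= 0):
        emit(i, j)
    return records


# --------------------------------------------------------------------------
# Top level
# --------------------------------------------------------------------------

@dataclass
class ShiftResult:
    """One simulated shift: the raw record stream plus its ground truth."""

    shift: ShiftSpec
    records: list[RawRecord]
    truth: list[TrueContact]
    trajectories: Trajectories


def simulate_shift(scenario: SimScenario, layout: Layout, shift: ShiftSpec,
                   with_truth: bool = True) -> ShiftResult:
    """Simulate one shift end to end (movement -> ground truth -> sensing)."""
    move_rng = np.random.default_rng([scenario.seed, shift.index, 0])
    sense_rng = np.random.default_rng([scenario.seed, shift.index, 1])
    traj = simulate_movement(scenario, layout, shift, move_rng)
    truth = (true_contacts(traj, scenario.contact_threshold_in)
             if with_truth else [])
    records = sense_and_emit(traj, scenario, sense_rng)
    return ShiftResult(shift=shift, records=records, truth=truth,
                       trajectories=traj)


def simulate(scenario: SimScenario,
             with_truth: bool = True) -> dict[int, ShiftResult]:
    """Simulate every shift of the scenario's plan, keyed by shift index."""
    layout = generate_layout(scenario)
    return {
        shift.index: simulate_shift(scenario, layout, shift, with_truth)
        for shift in scenario.shift_plan()
    }


def to_utc_export(records: list[RawRecord]) -> list[RawRecord]:
    """Re-express record times as acquisition-time UTC (local + 5 h).

    The pipeline itself works in naive local time; this helper emulates the
    timestamps as a cloud acquisition system would have stored them.
    """
    shift = _dt.timedelta(hours=UTC_OFFSET_H)
    return [RawRecord(r.reporter, r.detected, r.start_time + shift,
                      r.distance_in, r.duration_s) for r in records]
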