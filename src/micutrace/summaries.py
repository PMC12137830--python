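"""Shift-level descriptive statistics over imputed histories.

Covers the deployment's validation statistic -- the mean number of badges
detected per ten-minute interval of the day, split into day-shift and
night-shift series -- plus the dwell/transit queries the histories were
designed to answer: how long HCPs spend in patient rooms, and how long
nurses take to move directly between patient rooms.
"""

from __future__ import annotations

import datetime as _dt
import logging

import pandas as pd

from .records import BadgeId, History, Role, role_of

logger = logging.getLogger("micutrace")

__all__ = [
    "mean_badge_count_per_bin",
    "room_dwell_times",
    "transit_times",
    "plot_badge_counts",
]

_DAY_START_S = 7 * 3600     # day shifts run 07:00-19:00
_DAY_END_S = 19 * 3600


def _second_of_day(t: _dt.datetime) -> int:
    return t.hour * 3600 + t.minute * 60 + t.second


def mean_badge_count_per_bin(histories: list[History],
                             bin_s: int = 600) -> pd.DataFrame:
    """Mean number of HCP badges detected per time-of-day bin, by shift kind.

    A badge counts as detected in a bin when it has at least one second of
    contact (with any badge, HCP or anchor) intersecting the bin.  Counts
    are taken per history (each history covers each time-of-day at most
    once) and averaged separately over day-shift histories (even shift
    indices) and night-shift histories (odd indices).

    Returns a DataFrame indexed by bin start second-of-day with columns
    ``day`` and ``night``; bins outside a shift kind's 12-hour window are
    NaN for that kind.  ``bin_s`` must divide 86400 (600 s gives 144 bins).
    """
    if 86400 % bin_s:
        raise ValueError(f"bin_s={bin_s} does not divide 86400")
    n_bins = 86400 // bin_s

    sums = {"day": [0.0] * n_bins, "night": [0.0] * n_bins}
    n_hist = {"day": 0, "night": 0}
    for hist in histories:
        kind = "day" if hist.shift_index % 2 == 0 else "night"
        n_hist[kind] += 1
        per_bin: dict[int, set[BadgeId]] = {}
        for t, per_badge in hist.entries.items():
            if not per_badge:
                continue
            b = _second_of_day(t) // bin_s
            per_bin.setdefault(b, set()).update(per_badge)
        for b, badges in per_bin.items():
            sums[kind][b] += len(badges)

    index = [b * bin_s for b in range(n_bins)]
    df = pd.DataFrame(index=pd.Index(index, name="bin_start_s"))
    for kind in ("day", "night"):
        means = []
        for b in range(n_bins):
            start = b * bin_s
            in_window = (_DAY_START_S <= start < _DAY_END_S)
            covered = in_window if kind == "day" else not in_window
            if n_hist[kind] and covered:
                means.append(sums[kind][b] / n_hist[kind])
            else:
                means.append(float("nan"))
        df[kind] = means
    return df


def room_dwell_times(history: History) -> dict[BadgeId, dict[int, int]]:
    """Total seconds each HCP badge spends in each patient room.

    A badge dwells in room ``r`` at second ``t`` when its annotated state is
    ``{room r, inroom true}``.  Requires a history processed by the in-room
    state machine; raises otherwise.  Per badge, the sum over rooms never
    exceeds the shift length.
    """
    if not history.annotated:
        raise ValueError("history has not been annotated with in-room states")
    dwell: dict[BadgeId, dict[int, int]] = {}
    for per_badge in history.entries.values():
        for badge, entry in per_badge.items():
            if entry.state is not None and entry.state.inroom:
                rooms = dwell.setdefault(badge, {})
                rooms[entry.state.room] = rooms.get(entry.state.room, 0) + 1
    return dwell


def transit_times(history: History, role: Role) -> list[int]:
    """Durations of direct moves between two different patient rooms.

    For each badge of ``role``, every maximal gap between an inroom-true
    episode in one room and the next inroom-true episode in a *different*
    room (with no intervening inroom episode) yields one transit duration in
    seconds: the time from the end of the first episode to the start of the
    second.  Consecutive episodes in the same room emit nothing.
    """
    if not history.annotated:
        raise ValueError("history has not been annotated with in-room states")

    inroom_seconds: dict[BadgeId, list[tuple[_dt.datetime, int]]] = {}
    for t in sorted(history.entries):
        for badge, entry in history.entries[t].items():
            if entry.state is not None and entry.state.inroom:
                if role_of(badge) is role:
                    inroom_seconds.setdefault(badge, []).append((t, entry.state.room))

    transits: list[int] = []
    for badge, seq in inroom_seconds.items():
        prev_room: int | None = None
        prev_last: _dt.datetime | None = None
        for t, room in seq:
            if prev_room is not None and room != prev_room:
                gap = int((t - prev_last).total_seconds()) - 1
                transits.append(max(gap, 0))
            prev_room, prev_last = room, t
    return transits


def plot_badge_counts(df: pd.DataFrame, path) -> None:
    """Plot the day/night mean badge-count series against time of day."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    hours = df.index / 3600.0
    ax.plot(hours, df["day"], "o-", color="green", ms=3, label="day shifts")
    ax.plot(hours, df["night"], "s-", color="blue", ms=3, label="night shifts")
    ax.set_xlabel("time of day (h)")
    ax.set_ylabel("mean badge count")
    ax.set_xlim(0, 24)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
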