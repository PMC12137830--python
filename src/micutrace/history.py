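"""Per-second imputed contact histories and the in-room inference heuristic.

A history maps every second of one shift to each HCP badge's concurrent
contacts.  It is "imputed" because badges report intervals, not samples: a
badge is taken to be in contact with a partner at second ``t`` whenever some
contact interval for the pair contains ``t`` (half-open span convention).
Anchors are omitted as primary keys -- the goal is to track people -- but they
remain visible inside HCP contact lists, and symmetry is forced between HCP
pairs so each direction of a contact is always represented.

The in-room heuristic enriches each entry with a room-occupancy state:
contact with a patient room's *interior* anchor (sink, computer workstation
or vitals monitor) is taken as evidence of being in that room; contact with
the room's door anchor alone is not (an HCP may linger at the door without
entering).  The state clears as soon as the badge contacts any anchor
outside the room.
"""

from __future__ import annotations

import datetime as _dt
import logging

import networkx as nx

from .records import (
    INTERIOR_STATIONS,
    AnchorPlacement,
    BadgeId,
    History,
    HistoryEntry,
    PlacementError,
    RoomState,
    ShiftSpec,
    Station,
    role_of,
)

logger = logging.getLogger("micutrace")

__all__ = ["impute_history", "annotate_inroom", "contact_graph"]

_ONE_S = _dt.timedelta(seconds=1)


def impute_history(intervals, shift: ShiftSpec) -> History:
    """Impute the per-second contact history of one shift from its intervals.

    For each second ``t`` of the shift, every HCP badge participating in an
    interval whose span contains ``t`` gets an entry listing its partners
    (HCP or anchor).  Contacts are listed in order of first contact, then
    label, so serialization is deterministic.  Intervals between two anchors
    should not occur by placement design; they are logged and excluded.

    Storage is sparse: seconds with no contacts have no key in ``entries``.
    """
    epoch = shift.start
    n_seconds = shift.duration_s
    # per-offset sparse store; datetime keys materialized once at the end
    store: dict[int, dict[BadgeId, HistoryEntry]] = {}

    ordered = sorted(intervals, key=lambda iv: (iv.start_time, iv.reporter, iv.detected))
    for iv in ordered:
        a, b = iv.reporter, iv.detected
        a_anchor, b_anchor = a.is_anchor, b.is_anchor
        if a_anchor and b_anchor:
            logger.warning("anchor-anchor interval excluded from history: %s", iv)
            continue
        lo = int((iv.start_time - epoch).total_seconds())
        hi = lo + iv.duration_s
        lo, hi = max(lo, 0), min(hi, n_seconds)
        for k in range(lo, hi):
            per_badge = store.setdefault(k, {})
            # symmetry is forced: both HCP directions recorded; anchors are
            # never primary keys
            if not a_anchor:
                entry = per_badge.get(a)
                if entry is None:
                    entry = per_badge[a] = HistoryEntry()
                if b not in entry.contacts:
                    entry.contacts.append(b)
            if not b_anchor:
                entry = per_badge.get(b)
                if entry is None:
                    entry = per_badge[b] = HistoryEntry()
                if a not in entry.contacts:
                    entry.contacts.append(a)

    entries = {
        epoch + _dt.timedelta(seconds=k): per_badge
        for k, per_badge in sorted(store.items())
    }
    return History(shift_index=shift.index, entries=entries)


def _belongs_to_room(placement: AnchorPlacement, room: int,
                     door_clears_own_room: bool) -> bool:
    """Is this anchor 'inside' room (i.e. does contacting it NOT clear)?"""
    if placement.room != room or not isinstance(placement.room, int):
        return False
    if placement.station is Station.DOOR:
        return not door_clears_own_room
    return True


def annotate_inroom(history: History, placements: list[AnchorPlacement],
                    door_clears_own_room: bool = False) -> History:
    """Run the in-room state machine over every HCP badge of a history.

    Scanning each badge's entries in time order: contact with an interior
    anchor (sink/computer/vitals) of room ``r`` sets the state to
    ``{room r, inroom true}``; a later contact with any anchor *outside*
    room ``r`` clears the state; contact with room ``r``'s own door anchor
    leaves it unchanged (set ``door_clears_own_room`` to treat the own door
    as outside).  State is null at shift start and persists across seconds
    without anchor contact.

    If a badge simultaneously contacts interior anchors of two rooms, the
    room whose anchor contact began most recently wins; ties go to the
    smaller room number (logged).  The history is annotated in place and
    returned.
    """
    anchor_map: dict[BadgeId, AnchorPlacement] = {p.anchor: p for p in placements}

    per_badge_seconds: dict[BadgeId, list[_dt.datetime]] = {}
    for t in sorted(history.entries):
        for badge in history.entries[t]:
            per_badge_seconds.setdefault(badge, []).append(t)

    for badge, seconds in per_badge_seconds.items():
        state: RoomState | None = None
        episode_start: dict[BadgeId, _dt.datetime] = {}
        last_seen: dict[BadgeId, _dt.datetime] = {}
        for t in seconds:
            entry = history.entries[t][badge]
            anchors = [c for c in entry.contacts if c.is_anchor]
            contact_pl: list[tuple[BadgeId, AnchorPlacement]] = []
            for a in anchors:
                pl = anchor_map.get(a)
                if pl is None:
                    raise PlacementError(
                        f"anchor {a} contacted at {t} is absent from the placements"
                    )
                if last_seen.get(a) != t - _ONE_S:
                    episode_start[a] = t
                last_seen[a] = t
                contact_pl.append((a, pl))

            if state is not None and any(
                not _belongs_to_room(pl, state.room, door_clears_own_room)
                for _, pl in contact_pl
            ):
                state = None

            interior = [
                (a, pl) for a, pl in contact_pl
                if pl.station in INTERIOR_STATIONS and isinstance(pl.room, int)
            ]
            if interior:
                rooms = {pl.room for _, pl in interior}
                if len(rooms) > 1:
                    logger.info(
                        "%s contacts interior anchors of rooms %s at %s",
                        badge, sorted(rooms), t,
                    )
                # most recent episode wins; tie -> smaller room number
                a, pl = min(
                    interior, key=lambda ap: (-episode_start[ap[0]].timestamp(),
                                              ap[1].room),
                )
                state = RoomState(room=pl.room, inroom=True)

            entry.state = RoomState(state.room, state.inroom) if state else None

    history.annotated = True
    return history


def contact_graph(history: History, t0: _dt.datetime,
                  t1: _dt.datetime) -> nx.Graph:
    """Weighted contact graph over the window ``[t0, t1)``.

    Undirected edges connect badges with weight equal to their number of
    seconds of contact within the window; nodes carry a ``role`` attribute.
    Within one shift each node represents one healthcare professional (or
    anchor), since badges are not reused within a shift.  An empty window
    yields an empty graph.
    """
    g = nx.Graph()
    for t in sorted(history.entries):
        if not (t0 <= t < t1):
            continue
        pairs: set[tuple[BadgeId, BadgeId]] = set()
        for badge, entry in history.entries[t].items():
            for partner in entry.contacts:
                pairs.add((badge, partner) if badge <= partner else (partner, badge))
        for a, b in pairs:
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    for node in g.nodes:
        g.nodes[node]["role"] = role_of(node).value
    return g
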