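"""Construction of clean, symmetric contact intervals from raw badge records.

The raw stream holds two record types per contact: a start record
(duration 0) and an end record (duration > 0) that carries the *start* time
of the interval.  The collation procedure is:

1. drop records whose sensed distance is under 12 inches (badges stacked in
   a receptacle at shift handout/turn-in, not genuine HCP proximity);
2. match start records to end records sharing ``(reporter, detected,
   start_time)``; a lone start -- the badge firmware ignores contacts shorter
   than its 15-second processing cycle, so brief contacts never produce an
   end record -- becomes a substitute 10-second interval;
3. take the bidirectional union: badge clocks drift by some seconds, so the
   two directions of one physical contact may disagree slightly; overlapping
   (a, b) and (b, a) intervals are rewritten to the common span
   [min start, max end], and every interval is mirrored so that the presence
   of an (a, b) interval implies an identical (b, a) interval.
"""

from __future__ import annotations

import datetime as _dt
import logging
from collections import defaultdict
from dataclasses import dataclass, field

from .records import BadgeId, ContactInterval, RawRecord, ShiftSpec

logger = logging.getLogger("micutrace")

__all__ = [
    "MIN_DISTANCE_IN",
    "LONE_START_DURATION_S",
    "PairingResult",
    "filter_min_distance",
    "pair_start_end",
    "pair_start_end_detailed",
    "merge_bidirectional",
    "build_intervals",
    "split_by_shift",
]

#: distances below this many inches are receptacle artifacts, not contacts
MIN_DISTANCE_IN = 12

#: substitute duration for a start record with no matching end record
LONE_START_DURATION_S = 10


def filter_min_distance(records: list[RawRecord],
                        min_in: int = MIN_DISTANCE_IN) -> list[RawRecord]:
    """Keep records with sensed distance >= ``min_in`` inches, order preserved.

    The rule skips distances *less than* the threshold, so a record at
    exactly 12 inches survives the default filter.
    """
    return [r for r in records if r.distance_in >= min_in]


@dataclass
class PairingResult:
    """Outcome of start/end matching, with provenance for auditing."""

    intervals: list[ContactInterval] = field(default_factory=list)
    n_matched: int = 0
    n_lone_starts: int = 0
    n_orphan_ends: int = 0
    n_duplicates: int = 0

    @property
    def matched_intervals(self) -> list[ContactInterval]:
        return [iv for iv in self.intervals if iv.matched]


def pair_start_end_detailed(records: list[RawRecord]) -> PairingResult:
    """Match start records to end records into contact intervals.

    The matching key is ``(reporter, detected, start_time)`` exactly, since
    end records carry the interval's start time.  Outcomes per key:

    * start + end          -> interval with the end record's duration
                              (several ends: the largest duration wins, logged);
    * start alone          -> interval with the 10-second substitute duration;
    * end alone (orphan)   -> retained as an interval of its stated duration,
                              logged for audit;
    * exact duplicates     -> deduplicated with a log line.

    The result is sorted by start time, then (reporter, detected).
    """
    result = PairingResult()
    seen: set[RawRecord] = set()
    groups: dict[tuple, dict[str, list[RawRecord]]] = defaultdict(
        lambda: {"start": [], "end": []}
    )
    for rec in records:
        if rec in seen:
            result.n_duplicates += 1
            logger.info("duplicate record dropped: %s", rec)
            continue
        seen.add(rec)
        key = (rec.reporter, rec.detected, rec.start_time)
        groups[key]["start" if rec.is_start else "end"].append(rec)

    for (reporter, detected, start_time), bucket in groups.items():
        starts, ends = bucket["start"], bucket["end"]
        if ends:
            if len(ends) > 1:
                logger.info(
                    "%d end records for %s<-%s@%s; keeping the longest",
                    len(ends), reporter, detected, start_time,
                )
            end = max(ends, key=lambda r: r.duration_s)
            if starts:
                result.n_matched += 1
                distance = starts[0].distance_in
            else:
                result.n_orphan_ends += 1
                distance = end.distance_in
                logger.info("orphan end record retained: %s", end)
            result.intervals.append(ContactInterval(
                reporter=reporter, detected=detected, start_time=start_time,
                distance_in=distance, duration_s=end.duration_s,
                matched=bool(starts),
            ))
        elif starts:
            result.n_lone_starts += 1
            result.intervals.append(ContactInterval(
                reporter=reporter, detected=detected, start_time=start_time,
                distance_in=starts[0].distance_in,
                duration_s=LONE_START_DURATION_S, matched=False,
            ))

    result.intervals.sort(key=lambda iv: (iv.start_time, iv.reporter, iv.detected))
    return result


def pair_start_end(records: list[RawRecord]) -> list[ContactInterval]:
    """Shorthand for :func:`pair_start_end_detailed` returning the intervals."""
    return pair_start_end_detailed(records).intervals


def merge_bidirectional(intervals: list[ContactInterval],
                        slack_s: int = 0) -> list[ContactInterval]:
    """Union overlapping opposite-direction intervals and force mirror symmetry.

    For every badge pair (a, b), intervals whose half-open spans overlap an
    opposite-direction interval (within ``slack_s`` seconds of slack) are
    rewritten to the common span [min start, max end]; the rewriting is
    iterated to a fixpoint so chained overlaps coalesce into one span.  Every
    surviving span is then present in both directions with identical extent.

    Because mirroring makes every span bidirectional, the fixpoint equals the
    plain interval union (per unordered pair) of all spans from either
    direction, which is how it is computed here.  A merged span's distance is
    the minimum of its constituents' distances (closest approach).
    """
    spans: dict[tuple[BadgeId, BadgeId], list[tuple]] = defaultdict(list)
    for iv in intervals:
        a, b = sorted((iv.reporter, iv.detected))
        spans[(a, b)].append((iv.start_time, iv.end_time, iv.distance_in, iv.matched))

    slack = _dt.timedelta(seconds=slack_s)
    out: list[ContactInterval] = []
    for (a, b), items in spans.items():
        items.sort(key=lambda s: s[0])
        merged: list[list] = []
        for start, end, dist, matched in items:
            if merged and start <= merged[-1][1] + slack:
                merged[-1][1] = max(merged[-1][1], end)
                merged[-1][2] = min(merged[-1][2], dist)
                merged[-1][3] = merged[-1][3] or matched
            else:
                merged.append([start, end, dist, matched])
        for start, end, dist, matched in merged:
            duration = int((end - start).total_seconds())
            for rep, det in ((a, b), (b, a)):
                out.append(ContactInterval(
                    reporter=rep, detected=det, start_time=start,
                    distance_in=dist, duration_s=duration, matched=matched,
                ))
    out.sort(key=lambda iv: (iv.start_time, iv.reporter, iv.detected))
    return out


def build_intervals(raw: list[RawRecord],
                    min_distance_in: int = MIN_DISTANCE_IN,
                    merge_slack_s: int = 0) -> list[ContactInterval]:
    """Full collation: distance filter -> start/end pairing -> bidirectional union."""
    filtered = filter_min_distance(raw, min_distance_in)
    paired = pair_start_end(filtered)
    return merge_bidirectional(paired, slack_s=merge_slack_s)


def split_by_shift(intervals: list[ContactInterval],
                   shifts: list[ShiftSpec]) -> dict[int, list[ContactInterval]]:
    """Assign each interval to the shift containing its start time.

    Intervals starting outside every shift are dropped with a log line
    (badges are only valid within a single shift).
    """
    out: dict[int, list[ContactInterval]] = {s.index: [] for s in shifts}
    dropped = 0
    for iv in intervals:
        for shift in shifts:
            if shift.contains(iv.start_time):
                out[shift.index].append(iv)
                break
        else:
            dropped += 1
    if dropped:
        logger.info("%d intervals start outside all shifts; dropped", dropped)
    return out
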