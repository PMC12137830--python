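"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import datetime as dt
from collections import defaultdict

import pytest

import micutrace as mt

SHIFT2 = mt.ShiftSpec.from_index(2)   # a day shift, 07:00-19:00
T0 = SHIFT2.start


def rec(a: str, b: str, off: int, dist: int = 40, dur: int = 0,
        base: dt.datetime = T0) -> mt.RawRecord:
    """Raw record at ``base + off`` seconds."""
    return mt.RawRecord(mt.BadgeId(a), mt.BadgeId(b),
                        base + dt.timedelta(seconds=off), dist, dur)


def iv(a: str, b: str, off: int, dur: int, dist: int = 40,
       base: dt.datetime = T0, matched: bool = True) -> mt.ContactInterval:
    """Contact interval starting at ``base + off`` seconds."""
    return mt.ContactInterval(mt.BadgeId(a), mt.BadgeId(b),
                              base + dt.timedelta(seconds=off), dist, dur,
                              matched=matched)


# --------------------------------------------------------------------------
# Independent oracles
# --------------------------------------------------------------------------

def brute_merge_spans(intervals, slack_s: int = 0):
    """Literal fixpoint of the bidirectional-union rule, for cross-checking.

    Adds mirror copies, then repeatedly rewrites every opposite-direction
    overlapping (touching counts, plus slack) span pair to the common
    [min start, max end] with the minimum distance, until nothing changes.
    Returns ``{(reporter, detected): sorted set of (start, end, distance)}``.
    """
    slack = dt.timedelta(seconds=slack_s)
    spans = [[x.reporter, x.detected, x.start_time, x.end_time, x.distance_in]
             for x in intervals]
    changed = True
    while changed:
        changed = False
        uniq = {tuple(s) for s in spans}
        spans = [list(s) for s in sorted(uniq)]
        have = {(r, d, s, e) for r, d, s, e, _ in uniq}
        for r, d, s, e, dist in list(uniq):
            if (d, r, s, e) not in have:
                spans.append([d, r, s, e, dist])
                have.add((d, r, s, e))
                changed = True
        for i in range(len(spans)):
            for j in range(len(spans)):
                si, sj = spans[i], spans[j]
                if si[0] == sj[1] and si[1] == sj[0]:
                    if si[2] <= sj[3] + slack and sj[2] <= si[3] + slack:
                        ns, ne = min(si[2], sj[2]), max(si[3], sj[3])
                        nd = min(si[4], sj[4])
                        if (si[2], si[3], si[4]) != (ns, ne, nd) or \
                           (sj[2], sj[3], sj[4]) != (ns, ne, nd):
                            si[2:5] = [ns, ne, nd]
                            sj[2:5] = [ns, ne, nd]
                            changed = True
    out = defaultdict(set)
    for r, d, s, e, dist in map(tuple, spans):
        out[(r, d)].add((s, e, dist))
    return {k: sorted(v) for k, v in out.items()}


def merged_spans(intervals):
    """Spans of a merge_bidirectional result in the oracle's shape."""
    out = defaultdict(set)
    for x in intervals:
        out[(x.reporter, x.detected)].add((x.start_time, x.end_time, x.distance_in))
    return {k: sorted(v) for k, v in out.items()}


def brute_history(intervals, shift: mt.ShiftSpec):
    """Naive per-second scan: for each second, collect the intervals that
    contain it; HCP badges map to the set of their partners."""
    out: dict[dt.datetime, dict[str, set]] = {}
    for x in intervals:
        if x.reporter.is_anchor and x.detected.is_anchor:
            continue
        t = max(x.start_time, shift.start)
        while t < min(x.end_time, shift.end):
            per = out.setdefault(t, {})
            if not x.reporter.is_anchor:
                per.setdefault(x.reporter, set()).add(x.detected)
            if not x.detected.is_anchor:
                per.setdefault(x.detected, set()).add(x.reporter)
            t += dt.timedelta(seconds=1)
    return out


def history_as_sets(history: mt.History):
    return {
        t: {b: set(e.contacts) for b, e in per.items()}
        for t, per in history.entries.items()
    }


# --------------------------------------------------------------------------
# Simulated fixtures (kept small: a handful of agents, few rooms)
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_scenario() -> mt.SimScenario:
    return mt.SimScenario(
        seed=11,
        rooms=4,
        day_roster=mt.RosterCounts(2, 3, 2),
        night_roster=mt.RosterCounts(1, 2, 1),
        shift_indices=(2, 3),
    )


@pytest.fixture(scope="session")
def small_layout(small_scenario) -> mt.Layout:
    return mt.generate_layout(small_scenario)


@pytest.fixture(scope="session")
def sim_day(small_scenario, small_layout) -> mt.ShiftResult:
    """One simulated day shift with ground truth, shared across tests."""
    return mt.simulate_shift(small_scenario, small_layout, SHIFT2)
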