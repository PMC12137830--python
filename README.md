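# micutrace

Tools for processing and simulating proximity-badge contact data from a
hospital medical intensive care unit (MICU).

Healthcare-associated infections spread along contacts between healthcare
professionals (HCPs), patients, and the surfaces of a unit. One way to
measure those contacts is to instrument a unit with ultra-wideband (UWB)
proximity badges: every HCP wears a badge, and stationary *anchor* badges
mark locations of interest — each patient room's door, sink, computer
workstation and vitals monitor. A *contact* is two badges being within the
six-foot (72 in) threshold; badges record the start and end of contact
intervals with ~10 cm ranging accuracy, quantized by a 15-second on-badge
processing cycle and blurred by unsynchronized clocks.

`micutrace` implements the full chain from the raw badge records to
analysis-ready structures, plus an agent-based simulator that produces
format-identical synthetic raw data with ground truth, so every stage can be
validated without access to a real deployment:

| stage | module | what it does |
|---|---|---|
| records | `micutrace.records` | badge-label semantics, 5-field JSON(+xz) record I/O, history and anchor-placement formats, shift calendar |
| intervals | `micutrace.intervals` | distance filter (< 12 in dropped), start/end matching (lone starts → 10-s substitute intervals), bidirectional union forcing mirror symmetry |
| history | `micutrace.history` | per-second imputed contact history per shift, in-room state machine, weighted contact graphs |
| summaries | `micutrace.summaries` | mean badge count per ten-minute time-of-day bin (day vs night shifts), room dwell times, room-to-room transit times |
| simulator | `micutrace.simulator` | MICU layout generation, semi-Markov HCP mobility, UWB sensing model with clock drift, receptacle artifacts and ground-truth contacts |
| cli | `micutrace.cli` | `micutrace simulate / make-intervals / make-histories / annotate / summarize / graph / pipeline` |

## The core reconstruction

Raw data is a JSON array of 5-field records
`[reporter, detected, "datetime(Y,M,D,h,m,s)", distance_in, duration_s]`
where `duration_s = 0` marks the start of a contact and an end record
carries the *start* time of its interval. The collation is:

1. drop records with sensed distance < 12 in (badges stacked in a
   receptacle at shift handout/turn-in);
2. match starts to ends on `(reporter, detected, start_time)`; a matched
   interval's duration is a multiple of 15 s; a start with no end (the badge
   ignores contacts shorter than one processing cycle) becomes a 10-s
   interval;
3. union: an `(a, b)` interval overlapping a `(b, a)` interval is rewritten
   to `[min start, max end]` to a fixpoint, and every interval is mirrored,
   so `(a, b)` present implies an identical `(b, a)`.

From intervals, the imputed history `H[t][a]` lists badge `a`'s contacts at
every second `t` of a shift (anchors appear inside contact lists but never
as primary keys), and the in-room heuristic adds `a.room` / `a.inroom`:
contact with an interior anchor (sink/computer/vitals) of room *r* sets the
state; a later contact with any anchor outside room *r* clears it; the
room's own door anchor changes nothing.

## Worked example

Simulate one night shift of a 3-room unit with 3 HCPs (1 provider, 2
nurses, 1 support staff) and push it through the whole chain:

```python
import micutrace as mt
from micutrace.intervals import build_intervals, filter_min_distance, \
    pair_start_end_detailed
from micutrace.history import impute_history, annotate_inroom, contact_graph

sc = mt.SimScenario(seed=17, rooms=3,
                    day_roster=mt.RosterCounts(1, 2, 1),
                    night_roster=mt.RosterCounts(1, 1, 1),
                    shift_indices=(3,))
layout = mt.generate_layout(sc)
shift = mt.ShiftSpec.from_index(3)            # night shift, 19:00-07:00
res = mt.simulate_shift(sc, layout, shift)

pairing = pair_start_end_detailed(filter_min_distance(res.records))
ivs = build_intervals(res.records)
hist = annotate_inroom(
    impute_history([x for x in ivs if shift.contains(x.start_time)], shift),
    layout.placements)
```

prints, via the obvious `print` statements:

```
raw records:        4945
matched intervals:  1370
lone starts:        2006
merged intervals:   3698
busiest badge:      n017 spent 13940 s in room 1, 22584 s in room 2, 1414 s in room 3
shift contact graph: 15 badges, 39 edges
nurse transits:     57 direct moves, mean 28 s
```

The 4,945 raw records collapse to 1,370 matched start/end pairs (their
durations all multiples of 15 s) plus 2,006 lone starts kept as 10-second
stubs; after the bidirectional union every interval exists in both
directions. Badge `n017` is a nurse assigned to rooms 1-2, and the in-room
state machine credits her with roughly 3.9 and 6.3 hours at those bedsides.
The same artifacts are produced from the shell by
`micutrace pipeline --config demo.yaml` (see `micutrace pipeline --help`
for the config schema), with per-shift files named `intervalsXX.json.xz` /
`historiesXX.json.xz` and a manifest of parameter and artifact hashes.

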