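# Methods

This note records the models implemented by `micutrace`, their assumptions,
the defaults and why they were chosen, and what the synthetic-data tests do
and do not demonstrate about real deployments.

## Setting

A medical intensive care unit (MICU) of 26 single-occupancy patient rooms
is instrumented with UWB proximity badges. Worn badges are labelled by role
(`pr` provider, `n` nurse, `ss` support staff); stationary anchors (`b`)
mark each room's door, sink, computer workstation and vitals monitor, with
every pair of anchors more than six feet apart so anchors never contact
each other. Work is organized in 12-hour shifts (even indices day,
07:00–19:00; odd indices night); badges are reassigned randomly each
shift, so badge identity is only meaningful within one shift. All pipeline
times are naive local datetimes at one-second resolution; the five-hour
UTC offset of raw acquisition is modelled only in the simulator's export
helper.

## Interval collation

Raw records are 5-field JSON entries; `duration_s = 0` marks a contact
start, and end records carry the interval's *start* time, so the matching
key is exactly `(reporter, detected, start_time)`.

Decisions where the rules left room:

* **Distance filter boundary.** Records under 12 inches are receptacle
  artifacts (badges stacked together around shift handout/turn-in); the
  rule is "less than 12 inches", read literally as exclusive, so a record
  at exactly 12 in survives.
* **Several end records per key.** The largest duration wins; the rest are
  logged. Exact duplicate records are deduplicated with a log line.
* **Orphan end records.** An end with no start should not occur (only
  orphan *starts* are an expected artifact of the firmware ignoring brief
  contacts); they are conservatively retained as intervals of their stated
  duration and logged for audit rather than silently dropped.
* **Span convention.** Intervals are half-open `[start, start+duration)`.
  This makes per-second imputation and window additivity exact.
* **Union semantics.** The bidirectional union rewrites overlapping
  opposite-direction spans to `[min start, max end]` to a fixpoint and
  mirrors every span. Because mirroring makes every span bidirectional,
  the fixpoint equals the plain per-pair interval union, which is how it
  is computed; a brute-force fixpoint oracle in the test suite checks the
  equivalence on random instances. Abutting spans (one ends exactly where
  the other begins) are treated as one continuous contact. Merge slack
  defaults to 0 s and is configurable, because inter-badge clock drift is
  only known to be "some seconds".
* **Distance of a merged interval.** The minimum of the constituents'
  distances (closest approach) — conservative and deterministic.

## Imputed histories and in-room inference

The history maps each second of a shift to each HCP badge's concurrent
contacts. Anchors are omitted as primary keys (the goal is tracking
people) but remain visible inside contact lists; symmetry between HCP
pairs is forced. Storage is sparse — seconds without contacts carry no
key — while the external JSON format is accepted both sparse and dense.
Contacts are ordered by first-contact time, then label, so serialization
is deterministic.

The in-room state machine: contact with an interior anchor
(sink/computer/vitals) of room *r* sets `{room r, inroom true}`; a later
contact with any anchor outside room *r* clears it; the state is null at
shift start. Points the rule leaves open, and the defaults taken:

* **The room's own door anchor** neither sets (lingering at the door is
  not entering) nor clears (it is not "outside the patient room") the
  state. A flag (`door_clears_own_room`) provides the alternative reading,
  since the original convention is ambiguous.
* **Simultaneous interior anchors of two rooms** (pathological, possible
  only at threshold range through a wall): the room whose anchor contact
  began most recently wins; ties go to the smaller room number, logged.
* Within one second, clearing is applied before setting, so an interior
  contact in a new room takes over in the same second that it clears the
  old room.

Dwell time in a room counts seconds whose annotated state is inroom-true
(such seconds necessarily have at least one contact). A transit is the gap
between consecutive inroom episodes in two *different* rooms; consecutive
episodes in the same room emit nothing.

## The validation statistic

Mean badge count per time-of-day bin: a badge counts in a bin when it has
at least one second of contact (with any badge, HCP or anchor)
intersecting the bin; counts are averaged separately over day-shift and
night-shift histories. With 600-s bins a day has 144 bins — the only
self-consistent tiling of 24 hours by ten-minute intervals, which this
package uses even though the statistic is sometimes quoted with a slightly
larger bin count. Bins outside a shift kind's 12-hour window are reported
as NaN rather than zero, since no history of that kind covers them.

## Simulator

The simulator is the package's test bed: it must reproduce the *format and
failure modes* of the real acquisition, not any particular unit's traffic.

**Layout.** Rooms in two rows along a 10-ft corridor, 20×20 ft each, four
anchors per room at fixed station positions chosen so that all anchor
pairs — within and across rooms — are separated by more than six feet (the
constructor verifies this). Coordinates are exported in layout-image
pixels at 4 px/ft, the scale also used by the placement validator.

**Rosters and badges.** Day shifts field 12 providers / 19 nurses / 12
support staff; nights 6/15/8. Badges are drawn randomly each shift from
overprovisioned per-role pools (20/30/20), reproducing cross-shift badge
reuse without within-shift reuse. A configurable number of powered-on
unworn badges (default 2) sits in the handout receptacle and powers off
within half an hour of shift start.

**Mobility.** No mobility law is prescribed by the deployment, so the
model is a semi-Markov station-to-station process with role-specific
mixes: nurses are biased to one or two assigned rooms (62% assigned room,
25% nurse station), providers do rounds across rooms (58% random room),
support staff move sporadically with more corridor time. Dwell times are
gamma-distributed (mean 260 s for nurse room visits, 150 s provider, 120 s
support; clipped to [30, 1500] s); walking is rectilinear via the corridor
at 4 ft/s. Agents stand about two feet to the side of a station's anchor
(a worn badge is never on top of a wall-mounted one). These parameters are
plausible for a closed ICU but are conventions, not measurements.

**Handout/turn-in artifacts.** Before pickup (uniform within the first ten
minutes) and after turn-in (last few minutes), a badge sits in the
receptacle; when `receptacle_artifacts` is on, receptacle badges are
inches apart, generating the sub-12-inch records that the distance filter
exists to remove.

**Sensing.** Every `low_cycle_s` (default 3 s — the signaling period is
only known to be "a few seconds", so it is exposed in config) each badge
ranges all others with truncated-Gaussian distance noise (SD 4 in ≈ 10 cm,
the UWB accuracy). Every `high_cycle_s` (15 s) a processing cycle
reconciles contacts per directed pair:

* first under-threshold sample opens a contact; the start record carries
  that sample's time and sensed distance;
* a full cycle with no under-threshold sample purges the contact; an end
  record (duration = sample-support span rounded to the nearest multiple
  of 15 s) is written only if the support spanned at least one full cycle —
  shorter contacts leave a lone start record, and contacts shorter than
  the sampling period can be missed outright;
* contacts still open at shift end are purged as if scanned at turn-in.

Reported times are shifted by a constant per-badge integer clock offset
(uniform on ±5 s by default); ground truth stays on the global clock.
Consequences to keep in mind when interpreting recovery tests: matched
durations are quantized to 15 s (so a single contact's duration can be off
by up to ~8 s even noiselessly), and the sensor cannot resolve same-pair
gaps shorter than about two processing cycles — truth episodes that close
together are indistinguishable from one episode.

**Ground truth.** `TrueContact` episodes are maximal per-second runs of
true distance within the threshold, for all pairs except anchor–anchor.
Episode *counts* are not monotone in the threshold (a larger threshold can
merge two episodes into one), so the monotonicity checks in the tests are
on contacted pairs and per-pair contact seconds, which are monotone.

**Determinism.** All randomness flows from the scenario seed through
per-shift `numpy` generators; identical scenario and seed give identical
record streams, and the pipeline manifest records artifact hashes so
end-to-end reruns are verifiable.

## What the synthetic tests show — and what they do not

Passing recovery tests show that the *processing chain* is faithful: the
collation rules, union, imputation and in-room machine reconstruct what
the modelled sensor observed, within the sensor's own resolution. They do
not validate the mobility model against real HCP behaviour, radio
propagation effects (UWB largely avoids multipath, but the model has no
physics at all), badge loss or removal, or the actual traffic volumes of a
real unit. Recovery checks are scoped to contacts whose true distance
stays at or above 12 inches, because the distance filter removes
closer records by design.

## Problem sizes used in the checks

The bundled checks run on scaled units chosen to exercise every code path
with comfortable margins: format and rule checks on hand-built
micro-inputs; oracle comparisons on a few hundred random instances of up
to 10 badges and ~1000 s; recovery on a scripted noiseless hour of six
agents in an 8-room unit; and the day/night badge-count separation on two
full 12-hour shifts of a 26-room unit with the full deployment rosters.
The acceptance script simulates one day shift of a 6-room unit with a
3/5/3 roster, which yields on the order of 10,000 matched contacts.
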