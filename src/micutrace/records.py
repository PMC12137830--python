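"""Domain types and file formats for UWB badge contact data.

A deployment instruments a medical intensive care unit (MICU) with
ultra-wideband proximity badges.  Badges are either worn by healthcare
professionals (HCPs) or mounted at fixed stations ("anchors").  Each badge
records the start and end of *contact intervals* -- periods during which two
badges are within the contact distance threshold (six feet).

This module defines the badge-label conventions, the record/interval/history
container types, and readers and writers for the published JSON formats:

* raw records and contact intervals: a JSON array of 5-field records
  ``[reporter, detected, "datetime(Y,M,D,h,m,s)", distance_in, duration_s]``,
  optionally xz-compressed;
* imputed histories: a JSON object keyed by datetime strings, each value a
  mapping from HCP badge label to ``{"contacts": [...], "state": ...}``;
* anchor placements: a flat YAML mapping from anchor label to
  ``{room, station, x, y}`` in layout-image pixel coordinates.

All pipeline times are naive local datetimes at one-second resolution; the
acquisition-time UTC offset is a simulator export concern, not a pipeline one.
"""

from __future__ import annotations

import datetime as _dt
import enum
import json
import logging
import lzma
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence, Union

import yaml

logger = logging.getLogger("micutrace")

__all__ = [
    "FormatError",
    "PlacementError",
    "Role",
    "Station",
    "BadgeId",
    "role_of",
    "RawRecord",
    "ContactInterval",
    "RoomState",
    "HistoryEntry",
    "History",
    "AnchorPlacement",
    "ShiftSpec",
    "parse_datetime_string",
    "format_datetime",
    "parse_raw_records",
    "parse_intervals",
    "write_records",
    "read_history",
    "write_history",
    "load_placement",
    "write_placement",
]


class FormatError(ValueError):
    """A record, history or datetime string does not follow the file format."""


class PlacementError(ValueError):
    """An anchor placement file violates the placement invariants."""


# --------------------------------------------------------------------------
# Badge labels and roles
# --------------------------------------------------------------------------

class Role(str, enum.Enum):
    """Role of a badge, encoded in its label prefix."""

    ANCHOR = "anchor"       # b    -- stationary location beacon
    PROVIDER = "provider"   # pr   -- physician-capacity HCP
    NURSE = "nurse"         # n    -- nurse
    SUPPORT = "support"     # ss   -- support staff (therapist, clerk, ...)


#: label prefix -> role; longest prefixes first so "pr"/"ss" win over "p"/"s"
_PREFIX_ROLE: dict[str, Role] = {
    "pr": Role.PROVIDER,
    "ss": Role.SUPPORT,
    "b": Role.ANCHOR,
    "n": Role.NURSE,
}

_LABEL_RE = re.compile(r"^(pr|ss|b|n)(\d+)$")


class BadgeId(str):
    """A badge label such as ``"b037"``, ``"pr015"``, ``"n008"`` or ``"ss044"``.

    The label is a role prefix (``b`` anchor, ``pr`` provider, ``n`` nurse,
    ``ss`` support staff) followed by a zero-padded integer.  ``BadgeId`` is a
    ``str`` subclass so labels compare, hash and serialize as plain strings.
    """

    __slots__ = ()

    def __new__(cls, label: str) -> "BadgeId":
        if not _LABEL_RE.match(label):
            raise FormatError(f"invalid badge label: {label!r}")
        return super().__new__(cls, label)

    @property
    def role(self) -> Role:
        return role_of(self)

    @property
    def number(self) -> int:
        return int(_LABEL_RE.match(self).group(2))

    @property
    def is_anchor(self) -> bool:
        return role_of(self) is Role.ANCHOR

    @classmethod
    def make(cls, role: Role, number: int, width: int = 3) -> "BadgeId":
        """Build a canonical zero-padded label, e.g. ``make(NURSE, 8) -> n008``."""
        prefix = {v: k for k, v in _PREFIX_ROLE.items()}[role]
        return cls(f"{prefix}{number:0{width}d}")


def role_of(badge: str) -> Role:
    """Return the role encoded by a badge label's prefix.

    Raises :class:`FormatError` for labels with an unknown prefix or a
    non-numeric suffix.
    """
    m = _LABEL_RE.match(badge)
    if m is None:
        raise FormatError(f"invalid badge label: {badge!r}")
    return _PREFIX_ROLE[m.group(1)]


# --------------------------------------------------------------------------
# Datetime string dialect
# --------------------------------------------------------------------------

# liberal on input: optional quotes (straight or typographic) and optional
# whitespace after commas; strict canonical form on output.
_DT_RE = re.compile(
    r"""^["'“”]?\s*datetime\(\s*
        (\d+)\s*,\s*(\d+)\s*,\s*(\d+)\s*,\s*
        (\d+)\s*,\s*(\d+)\s*,\s*(\d+)\s*\)\s*["'“”]?$""",
    re.VERBOSE,
)


def parse_datetime_string(s: str) -> _dt.datetime:
    """Parse the file dialect ``datetime(Y,M,D,h,m,s)`` into a naive datetime."""
    m = _DT_RE.match(s.strip())
    if m is None:
        raise FormatError(f"unparseable datetime string: {s!r}")
    try:
        return _dt.datetime(*(int(g) for g in m.groups()))
    except ValueError as exc:
        raise FormatError(f"invalid datetime components in {s!r}: {exc}") from exc


def format_datetime(t: _dt.datetime) -> str:
    """Canonical no-space serialization, e.g. ``datetime(2023,4,25,7,39,43)``."""
    return f"datetime({t.year},{t.month},{t.day},{t.hour},{t.minute},{t.second})"


# --------------------------------------------------------------------------
# Records and intervals
# --------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class RawRecord:
    """One badge observation: the start or end of a contact.

    ``duration_s == 0`` marks the start of a contact; ``duration_s > 0`` marks
    the end.  End-of-interval records carry the *start* time of the interval,
    not the end time, so a start record and its matching end record share the
    same ``(reporter, detected, start_time)`` key.
    """

    reporter: BadgeId
    detected: BadgeId
    start_time: _dt.datetime
    distance_in: int
    duration_s: int

    def __post_init__(self) -> None:
        if self.distance_in < 0:
            raise FormatError(f"negative distance: {self.distance_in}")
        if self.duration_s < 0:
            raise FormatError(f"negative duration: {self.duration_s}")

    @property
    def is_start(self) -> bool:
        return self.duration_s == 0

    def to_fields(self) -> list:
        return [
            str(self.reporter),
            str(self.detected),
            format_datetime(self.start_time),
            int(self.distance_in),
            int(self.duration_s),
        ]

    @classmethod
    def from_fields(cls, fields: Sequence) -> "RawRecord":
        if len(fields) != 5:
            raise FormatError(f"expected 5 fields, got {len(fields)}")
        reporter, detected, when, dist, dur = fields
        return cls(
            reporter=BadgeId(reporter),
            detected=BadgeId(detected),
            start_time=parse_datetime_string(when),
            distance_in=int(dist),
            duration_s=int(dur),
        )


@dataclass(frozen=True, order=True)
class ContactInterval:
    """A reconstructed period of continuous sub-threshold proximity.

    ``duration_s`` is always positive: intervals built from a matched
    start/end record pair have durations that are multiples of the 15-second
    badge processing cycle, while intervals imputed from a lone start record
    carry the substitute duration of 10 seconds.  The time span convention is
    half-open, ``[start_time, start_time + duration_s)``.
    """

    reporter: BadgeId
    detected: BadgeId
    start_time: _dt.datetime
    distance_in: int
    duration_s: int
    #: bookkeeping only (not serialized, ignored by equality): whether this
    #: interval came from a matched start+end pair.
    matched: bool = field(default=True, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise FormatError(
                f"contact interval duration must be positive, got {self.duration_s}"
            )
        if self.distance_in < 0:
            raise FormatError(f"negative distance: {self.distance_in}")

    @property
    def end_time(self) -> _dt.datetime:
        return self.start_time + _dt.timedelta(seconds=self.duration_s)

    def to_fields(self) -> list:
        return [
            str(self.reporter),
            str(self.detected),
            format_datetime(self.start_time),
            int(self.distance_in),
            int(self.duration_s),
        ]

    @classmethod
    def from_fields(cls, fields: Sequence) -> "ContactInterval":
        if len(fields) != 5:
            raise FormatError(f"expected 5 fields, got {len(fields)}")
        reporter, detected, when, dist, dur = fields
        return cls(
            reporter=BadgeId(reporter),
            detected=BadgeId(detected),
            start_time=parse_datetime_string(when),
            distance_in=int(dist),
            duration_s=int(dur),
        )


PathLike = Union[str, Path]
Source = Union[PathLike, IO]


def _open_read(source: Source, compressed: bool | None):
    """Open ``source`` for text reading, transparently decompressing xz."""
    if hasattr(source, "read"):
        data = source.read()
        if isinstance(data, str):
            return data
        if compressed is None:
            compressed = data[:6] == b"\xfd7zXZ\x00"
        if compressed:
            data = lzma.decompress(data)
        return data.decode("utf-8")
    path = Path(source)
    if compressed is None:
        compressed = path.suffix == ".xz"
    if compressed:
        with lzma.open(path, "rt", encoding="utf-8") as fh:
            return fh.read()
    return path.read_text(encoding="utf-8")


def _write_text(text: str, path: PathLike, compressed: bool | None) -> None:
    path = Path(path)
    if compressed is None:
        compressed = path.suffix == ".xz"
    path.parent.mkdir(parents=True, exist_ok=True)
    if compressed:
        with lzma.open(path, "wt", encoding="utf-8") as fh:
            fh.write(text)
    else:
        path.write_text(text, encoding="utf-8")


def _parse_record_array(source, compressed, cls, lenient):
    text = _open_read(source, compressed)
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"not a JSON document: {exc}") from exc
    if not isinstance(raw, list):
        raise FormatError("top-level JSON value must be an array of records")
    out = []
    for i, item in enumerate(raw):
        try:
            if not isinstance(item, (list, tuple)):
                raise FormatError(f"record is not an array: {item!r}")
            out.append(cls.from_fields(item))
        except (FormatError, ValueError, TypeError) as exc:
            if lenient:
                logger.warning("skipping malformed record %d: %s", i, exc)
                continue
            raise FormatError(f"record {i}: {exc}") from exc
    return out


def parse_raw_records(
    source: Source,
    compressed: bool | None = None,
    lenient: bool = False,
) -> list[RawRecord]:
    """Parse a raw-record file (JSON array of 5-field records).

    Parameters
    ----------
    source:
        Path or open file/byte stream.  ``.xz`` paths and xz byte streams are
        decompressed automatically; pass ``compressed`` to override.
    lenient:
        When true, malformed records are logged and skipped instead of
        raising :class:`FormatError` with the offending record index.

    Records are returned in file order; the published files are not
    necessarily time-sorted and no sortedness is assumed.
    """
    return _parse_record_array(source, compressed, RawRecord, lenient)


def parse_intervals(
    source: Source,
    compressed: bool | None = None,
    lenient: bool = False,
) -> list[ContactInterval]:
    """Parse a contact-interval file (same 5-field layout, duration > 0)."""
    return _parse_record_array(source, compressed, ContactInterval, lenient)


def write_records(
    records: Iterable[Union[RawRecord, ContactInterval]],
    path: PathLike,
    compressed: bool | None = None,
) -> None:
    """Write records or intervals as a JSON array in the 5-field layout.

    ``parse_raw_records(write_records(X)) == X`` for any valid record list;
    xz compression is applied for ``.xz`` paths or when ``compressed=True``.
    """
    rows = [r.to_fields() for r in records]
    text = json.dumps(rows, separators=(", ", ": "))
    _write_text(text, path, compressed)


# --------------------------------------------------------------------------
# Histories
# --------------------------------------------------------------------------

@dataclass
class RoomState:
    """Inferred patient-room occupancy: room number plus the inroom flag."""

    room: int
    inroom: bool

    def to_json(self) -> dict:
        return {"room": self.room, "inroom": self.inroom}

    @classmethod
    def from_json(cls, obj: Mapping) -> "RoomState":
        return cls(room=int(obj["room"]), inroom=bool(obj["inroom"]))


@dataclass
class HistoryEntry:
    """One HCP badge's status at one second: concurrent contacts + room state."""

    __slots__ = ("contacts", "state")

    contacts: list[BadgeId]
    state: RoomState | None

    def __init__(self, contacts: list[BadgeId] | None = None,
                 state: RoomState | None = None) -> None:
        self.contacts = list(contacts) if contacts else []
        self.state = state

    def __eq__(self, other) -> bool:
        if not isinstance(other, HistoryEntry):
            return NotImplemented
        return self.contacts == other.contacts and self.state == other.state

    def __repr__(self) -> str:
        return f"HistoryEntry(contacts={self.contacts!r}, state={self.state!r})"


@dataclass
class History:
    """Per-second imputed contact history for one shift.

    ``entries`` maps each second (a naive datetime) to a mapping from HCP
    badge label to :class:`HistoryEntry`.  Anchors never appear as primary
    keys -- their contacts are visible only inside HCP contact lists.  Storage
    is sparse: seconds during which no badge has a contact are absent.
    """

    shift_index: int = 0
    entries: dict[_dt.datetime, dict[BadgeId, HistoryEntry]] = field(default_factory=dict)
    #: True once the in-room state machine has been run over the history.
    annotated: bool = False

    def seconds(self) -> list[_dt.datetime]:
        return sorted(self.entries)

    def span(self) -> tuple[_dt.datetime, _dt.datetime] | None:
        if not self.entries:
            return None
        ts = self.entries.keys()
        return min(ts), max(ts) + _dt.timedelta(seconds=1)

    def badges(self) -> set[BadgeId]:
        out: set[BadgeId] = set()
        for per_badge in self.entries.values():
            out.update(per_badge)
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, History):
            return NotImplemented
        return self.shift_index == other.shift_index and self.entries == other.entries


def write_history(history: History, path: PathLike,
                  compressed: bool | None = None) -> None:
    """Serialize a history to the published JSON-object layout.

    Keys are canonical datetime strings in time order; per-second badge keys
    are sorted, so serialization is deterministic.
    """
    obj: dict[str, dict] = {}
    for t in sorted(history.entries):
        per_badge = history.entries[t]
        obj[format_datetime(t)] = {
            str(b): {
                "contacts": [str(c) for c in per_badge[b].contacts],
                "state": None if per_badge[b].state is None
                else per_badge[b].state.to_json(),
            }
            for b in sorted(per_badge)
        }
    _write_text(json.dumps(obj, separators=(", ", ": ")), path, compressed)


def read_history(source: Source, shift_index: int = 0,
                 compressed: bool | None = None) -> History:
    """Read a history file back into a :class:`History`.

    Seconds with an empty badge map are accepted but stored sparsely.
    An anchor label appearing as a primary key is a format violation.
    """
    text = _open_read(source, compressed)
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"not a JSON document: {exc}") from exc
    if not isinstance(raw, dict):
        raise FormatError("top-level JSON value must be an object keyed by datetimes")
    entries: dict[_dt.datetime, dict[BadgeId, HistoryEntry]] = {}
    annotated = False
    for when, per_badge in raw.items():
        t = parse_datetime_string(when)
        if not per_badge:
            continue
        dest: dict[BadgeId, HistoryEntry] = {}
        for label, payload in per_badge.items():
            badge = BadgeId(label)
            if badge.is_anchor:
                raise FormatError(
                    f"anchor {badge} appears as a primary history key at {when}"
                )
            state = payload.get("state")
            if state is not None:
                state = RoomState.from_json(state)
                annotated = True
            dest[badge] = HistoryEntry(
                contacts=[BadgeId(c) for c in payload.get("contacts", [])],
                state=state,
            )
        entries[t] = dest
    return History(shift_index=shift_index, entries=entries, annotated=annotated)


# --------------------------------------------------------------------------
# Anchor placements
# --------------------------------------------------------------------------

class Station(str, enum.Enum):
    """Where an anchor is mounted."""

    DOOR = "door"
    SINK = "sink"
    COMPUTER = "computer"
    VITALS = "vitals"
    COMMON = "common"       # common-area anchor outside patient rooms


#: interior stations: contacting one implies the badge is inside the room
INTERIOR_STATIONS = frozenset({Station.SINK, Station.COMPUTER, Station.VITALS})

#: default layout-image scale used for the anchor-separation check
DEFAULT_PIXELS_PER_FOOT = 4.0

#: minimum anchor separation: the six-foot contact threshold, in inches
ANCHOR_MIN_SEPARATION_IN = 72.0


@dataclass(frozen=True)
class AnchorPlacement:
    """One anchor badge's room, station type and layout-image position."""

    anchor: BadgeId
    room: int | str
    station: Station
    x: float
    y: float

    def __post_init__(self) -> None:
        if role_of(self.anchor) is not Role.ANCHOR:
            raise PlacementError(f"{self.anchor} is not an anchor label")
        if self.station is Station.COMMON and isinstance(self.room, int):
            raise PlacementError(
                f"{self.anchor}: common-area anchors take an area label, not a room number"
            )


def _validate_placements(placements: Sequence[AnchorPlacement],
                         pixels_per_foot: float) -> None:
    problems: list[str] = []
    seen: set[BadgeId] = set()
    for p in placements:
        if p.anchor in seen:
            problems.append(f"duplicate anchor {p.anchor}")
        seen.add(p.anchor)
    # every patient room carries exactly one anchor of each of the four types
    rooms: dict[int, list[Station]] = {}
    for p in placements:
        if isinstance(p.room, int):
            rooms.setdefault(p.room, []).append(p.station)
    required = {Station.DOOR, Station.SINK, Station.COMPUTER, Station.VITALS}
    for room, stations in sorted(rooms.items()):
        missing = required - set(stations)
        if missing:
            problems.append(
                f"room {room} missing station(s): {sorted(s.value for s in missing)}"
            )
        dupes = [s for s in required if stations.count(s) > 1]
        if dupes:
            problems.append(
                f"room {room} has duplicate station(s): {sorted(s.value for s in dupes)}"
            )
    # no two anchors within six feet of each other (pixel coords -> inches)
    inches_per_px = 12.0 / pixels_per_foot
    for i, a in enumerate(placements):
        for b in placements[i + 1:]:
            d = math.hypot(a.x - b.x, a.y - b.y) * inches_per_px
            if d < ANCHOR_MIN_SEPARATION_IN:
                problems.append(
                    f"anchors {a.anchor} and {b.anchor} are {d:.1f} in apart "
                    f"(< {ANCHOR_MIN_SEPARATION_IN:.0f} in)"
                )
    if problems:
        raise PlacementError("; ".join(problems))


def load_placement(source: Source,
                   pixels_per_foot: float | None = None) -> list[AnchorPlacement]:
    """Load and validate an anchor placement file.

    The file is a flat YAML mapping from anchor label to ``{room, station,
    x, y}`` with an optional top-level ``pixels_per_foot`` scale (default
    4 px/ft) used for the six-foot anchor-separation check.
    """
    text = _open_read(source, None)
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise PlacementError("placement file must be a mapping")
    scale = float(raw.pop("pixels_per_foot", DEFAULT_PIXELS_PER_FOOT))
    if pixels_per_foot is not None:
        scale = pixels_per_foot
    placements = []
    for label, fields in raw.items():
        try:
            room = fields["room"]
            placements.append(AnchorPlacement(
                anchor=BadgeId(label),
                room=int(room) if isinstance(room, (int, float)) or str(room).isdigit()
                else str(room),
                station=Station(fields["station"]),
                x=float(fields["x"]),
                y=float(fields["y"]),
            ))
        except (KeyError, ValueError, TypeError) as exc:
            raise PlacementError(f"anchor {label}: {exc}") from exc
    _validate_placements(placements, scale)
    return placements


def write_placement(placements: Sequence[AnchorPlacement], path: PathLike,
                    pixels_per_foot: float = DEFAULT_PIXELS_PER_FOOT) -> None:
    """Write placements in the flat YAML dialect read by :func:`load_placement`."""
    obj: dict = {"pixels_per_foot": pixels_per_foot}
    for p in sorted(placements, key=lambda p: p.anchor):
        obj[str(p.anchor)] = {
            "room": p.room,
            "station": p.station.value,
            "x": p.x,
            "y": p.y,
        }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(obj, sort_keys=False), encoding="utf-8")


# --------------------------------------------------------------------------
# Shifts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ShiftSpec:
    """One 12-hour shift.  Even indices are day shifts (07:00-19:00), odd
    indices are night shifts (19:00-07:00 the next day)."""

    index: int
    start: _dt.datetime
    end: _dt.datetime

    def __post_init__(self) -> None:
        if self.end - self.start != _dt.timedelta(hours=12):
            raise ValueError("a shift spans exactly 12 hours")
        expected_hour = 7 if self.index % 2 == 0 else 19
        if self.start.hour != expected_hour:
            raise ValueError(
                f"shift {self.index} ({self.kind}) must start at {expected_hour}:00"
            )

    @property
    def kind(self) -> str:
        return "day" if self.index % 2 == 0 else "night"

    @property
    def duration_s(self) -> int:
        return int((self.end - self.start).total_seconds())

    @classmethod
    def from_index(cls, index: int,
                   first_day: _dt.date = _dt.date(2023, 4, 21)) -> "ShiftSpec":
        """Shift ``index`` of a study whose shift 0 is the day shift of
        ``first_day``; two shifts per calendar day."""
        day = first_day + _dt.timedelta(days=index // 2)
        hour = 7 if index % 2 == 0 else 19
        start = _dt.datetime.combine(day, _dt.time(hour, 0, 0))
        return cls(index=index, start=start, end=start + _dt.timedelta(hours=12))

    def contains(self, t: _dt.datetime) -> bool:
        return self.start <= t < self.end
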