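"""Observational data model and delimited-text readers/writers.

All tables are comma-separated UTF-8 text with a header row.  Identifier
lists inside a single field (the two proximity rings of a scan) are joined
with ``;``.  Timestamps are stored as a study-day integer plus an ``HH:MM``
clock string; all window arithmetic elsewhere in the package uses the
study-day component only.

Schemas
-------
roster.csv   id, sex, age_class
scans.csv    focal_id, focal_female, day, clock, males_2m, males_5m
events.csv   event_id, type, actor, recipient, day, clock, duration_s,
             surreptitious, protocol, focal_id
states.csv   female, day, state
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import InvariantError, RecordLinkError, SchemaError

__all__ = [
    "Sex",
    "AgeClass",
    "ReproductiveState",
    "BehaviourType",
    "Protocol",
    "Timestamp",
    "Individual",
    "ScanRecord",
    "BehaviourEvent",
    "FocalSample",
    "read_roster",
    "write_roster",
    "read_scans",
    "write_scans",
    "read_events",
    "write_events",
    "read_states",
    "write_states",
    "assemble_focals",
]


class Sex(enum.Enum):
    FEMALE = "F"
    MALE = "M"


class AgeClass(enum.Enum):
    ADULT = "ADULT"
    SUBADULT = "SUBADULT"


class ReproductiveState(enum.Enum):
    """Lactating, pregnant, or one of four graded swelling stages."""

    L = "L"
    P = "P"
    C0 = "C0"
    C1 = "C1"
    C2 = "C2"
    C3 = "C3"

    @property
    def tumescent(self) -> bool:
        return self in (ReproductiveState.C1, ReproductiveState.C2, ReproductiveState.C3)


#: C-stages in swelling order; used by the simulator's cycle chain.
CYCLE_STAGES = (
    ReproductiveState.C0,
    ReproductiveState.C1,
    ReproductiveState.C2,
    ReproductiveState.C3,
)


class BehaviourType(enum.Enum):
    APPROACH = "APPROACH"
    RETREAT = "RETREAT"
    SUPPLANT = "SUPPLANT"
    GROOM = "GROOM"
    GREET = "GREET"
    AGGRESSION = "AGGRESSION"
    COPULATION = "COPULATION"
    INFANT_HANDLING = "INFANT_HANDLING"


#: Event types that count as affiliative for transfer detection.
AFFILIATIVE_TYPES = frozenset(
    {BehaviourType.GROOM, BehaviourType.GREET, BehaviourType.COPULATION}
)


class Protocol(enum.Enum):
    FOCAL = "FOCAL"
    AD_LIBITUM = "AD_LIBITUM"


@dataclass(frozen=True, order=True)
class Timestamp:
    """Study-day integer plus minute-of-day (0..1439)."""

    day: int
    minute: int

    def __post_init__(self) -> None:
        if self.day < 1:
            raise InvariantError(f"study day must be >= 1, got {self.day}")
        if not 0 <= self.minute < 24 * 60:
            raise InvariantError(f"minute of day out of range: {self.minute}")

    @property
    def clock(self) -> str:
        return f"{self.minute // 60:02d}:{self.minute % 60:02d}"

    @classmethod
    def from_clock(cls, day: int, clock: str) -> "Timestamp":
        try:
            hh, mm = clock.split(":")
            minute = int(hh) * 60 + int(mm)
        except ValueError as exc:
            raise SchemaError(f"bad clock string {clock!r}") from exc
        return cls(day=day, minute=minute)

    def shifted(self, minutes: int) -> "Timestamp":
        total = self.minute + minutes
        return Timestamp(day=self.day + total // (24 * 60), minute=total % (24 * 60))


@dataclass(frozen=True)
class Individual:
    id: str
    sex: Sex
    age_class: AgeClass


@dataclass(frozen=True)
class ScanRecord:
    """One instantaneous proximity scan of a focal female.

    ``males_2m`` holds males at <= 2 m; ``males_5m`` the (2 m, 5 m] annulus.
    The two rings are disjoint by construction of the field protocol.
    """

    focal_female: str
    time: Timestamp
    males_2m: frozenset[str]
    males_5m: frozenset[str]
    focal_id: str = ""

    def __post_init__(self) -> None:
        overlap = self.males_2m & self.males_5m
        if overlap:
            raise InvariantError(
                f"ids present in both proximity rings: {sorted(overlap)}"
            )


@dataclass(frozen=True)
class BehaviourEvent:
    type: BehaviourType
    actor: str
    recipient: str
    time: Timestamp
    duration_s: float | None = None
    surreptitious: bool = False
    protocol: Protocol = Protocol.FOCAL
    focal_id: str = ""
    event_id: str = ""

    def __post_init__(self) -> None:
        if self.actor == self.recipient:
            raise InvariantError(f"actor == recipient ({self.actor})")
        if (self.duration_s is not None) != (self.type is BehaviourType.GROOM):
            raise InvariantError("duration_s present iff type is GROOM")
        if self.duration_s is not None and self.duration_s < 0:
            raise InvariantError("duration_s must be non-negative")

    def participants(self) -> frozenset[str]:
        return frozenset((self.actor, self.recipient))


@dataclass(frozen=True)
class FocalSample:
    """A 30-min focal follow: 4 scans at 10-min spacing plus its events."""

    focal_id: str
    focal_female: str
    start_time: Timestamp
    state: ReproductiveState
    scans: tuple[ScanRecord, ...]
    events: tuple[BehaviourEvent, ...] = ()
    duration_min: int = 30

    def __post_init__(self) -> None:
        if len(self.scans) != 4:
            raise InvariantError(f"focal sample needs exactly 4 scans, got {len(self.scans)}")
        for i, scan in enumerate(self.scans):
            expected = self.start_time.shifted(10 * i)
            if scan.time != expected:
                raise InvariantError(
                    f"scan {i} at {scan.time}, expected {expected} (10-min spacing)"
                )
            if scan.focal_female != self.focal_female:
                raise InvariantError("scan focal female differs from sample focal female")


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------

_ROSTER_HEADER = ["id", "sex", "age_class"]
_SCANS_HEADER = ["focal_id", "focal_female", "day", "clock", "males_2m", "males_5m"]
_EVENTS_HEADER = [
    "event_id",
    "type",
    "actor",
    "recipient",
    "day",
    "clock",
    "duration_s",
    "surreptitious",
    "protocol",
    "focal_id",
]
_STATES_HEADER = ["female", "day", "state"]


def _check_header(row: Sequence[str] | None, expected: Sequence[str], path: Path) -> None:
    if row is None or list(row) != list(expected):
        raise SchemaError(f"{path}: header {row} does not match {list(expected)}")


def _open_reader(path: str | Path):
    return open(path, "r", encoding="utf-8", newline="")


def _open_writer(path: str | Path):
    return open(path, "w", encoding="utf-8", newline="")


def _parse_enum(cls, token: str, path: Path, line: int):
    try:
        return cls(token)
    except ValueError as exc:
        raise SchemaError(f"{path}:{line}: unknown {cls.__name__} token {token!r}") from exc


def read_roster(path: str | Path) -> list[Individual]:
    path = Path(path)
    out: list[Individual] = []
    seen: set[str] = set()
    with _open_reader(path) as fh:
        reader = csv.reader(fh)
        _check_header(next(reader, None), _ROSTER_HEADER, path)
        for line, row in enumerate(reader, start=2):
            if len(row) != 3:
                raise SchemaError(f"{path}:{line}: expected 3 fields, got {len(row)}")
            ind_id, sex, age = row
            if not ind_id:
                raise SchemaError(f"{path}:{line}: empty id")
            if ind_id in seen:
                raise SchemaError(f"{path}:{line}: duplicate id {ind_id!r}")
            seen.add(ind_id)
            out.append(
                Individual(
                    id=ind_id,
                    sex=_parse_enum(Sex, sex, path, line),
                    age_class=_parse_enum(AgeClass, age, path, line),
                )
            )
    return out


def write_roster(path: str | Path, roster: Iterable[Individual]) -> None:
    with _open_writer(path) as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_ROSTER_HEADER)
        for ind in roster:
            writer.writerow([ind.id, ind.sex.value, ind.age_class.value])


def _split_ids(token: str) -> frozenset[str]:
    return frozenset(t for t in token.split(";") if t)


def _join_ids(ids: frozenset[str]) -> str:
    return ";".join(sorted(ids))


def read_scans(path: str | Path, roster: Sequence[Individual]) -> list[ScanRecord]:
    path = Path(path)
    by_id = {ind.id: ind for ind in roster}
    females = {
        ind.id
        for ind in roster
        if ind.sex is Sex.FEMALE and ind.age_class is AgeClass.ADULT
    }
    out: list[ScanRecord] = []
    with _open_reader(path) as fh:
        reader = csv.reader(fh)
        _check_header(next(reader, None), _SCANS_HEADER, path)
        for line, row in enumerate(reader, start=2):
            if len(row) != 6:
                raise SchemaError(f"{path}:{line}: expected 6 fields, got {len(row)}")
            focal_id, female, day, clock, ring2, ring5 = row
            if female not in females:
                raise RecordLinkError(
                    f"{path}:{line}: focal female {female!r} is not an adult female in the roster"
                )
            males_2m, males_5m = _split_ids(ring2), _split_ids(ring5)
            for mid in males_2m | males_5m:
                ind = by_id.get(mid)
                if ind is None:
                    raise RecordLinkError(f"{path}:{line}: unknown id {mid!r}")
                if ind.sex is not Sex.MALE:
                    raise RecordLinkError(f"{path}:{line}: ring id {mid!r} is not male")
            try:
                scan = ScanRecord(
                    focal_female=female,
                    time=Timestamp.from_clock(int(day), clock),
                    males_2m=males_2m,
                    males_5m=males_5m,
                    focal_id=focal_id,
                )
            except InvariantError as exc:
                raise InvariantError(f"{path}:{line}: {exc}") from exc
            out.append(scan)
    return out


def write_scans(path: str | Path, scans: Iterable[ScanRecord]) -> None:
    with _open_writer(path) as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_SCANS_HEADER)
        for scan in scans:
            writer.writerow(
                [
                    scan.focal_id,
                    scan.focal_female,
                    scan.time.day,
                    scan.time.clock,
                    _join_ids(scan.males_2m),
                    _join_ids(scan.males_5m),
                ]
            )


def read_events(path: str | Path, roster: Sequence[Individual]) -> list[BehaviourEvent]:
    path = Path(path)
    known = {ind.id for ind in roster}
    out: list[BehaviourEvent] = []
    with _open_reader(path) as fh:
        reader = csv.reader(fh)
        _check_header(next(reader, None), _EVENTS_HEADER, path)
        for line, row in enumerate(reader, start=2):
            if len(row) != 10:
                raise SchemaError(f"{path}:{line}: expected 10 fields, got {len(row)}")
            (event_id, etype, actor, recipient, day, clock,
             duration, surrept, protocol, focal_id) = row
            for pid in (actor, recipient):
                if pid not in known:
                    raise RecordLinkError(f"{path}:{line}: unknown id {pid!r}")
            if surrept not in ("0", "1"):
                raise SchemaError(f"{path}:{line}: surreptitious must be 0/1, got {surrept!r}")
            try:
                event = BehaviourEvent(
                    type=_parse_enum(BehaviourType, etype, path, line),
                    actor=actor,
                    recipient=recipient,
                    time=Timestamp.from_clock(int(day), clock),
                    duration_s=float(duration) if duration else None,
                    surreptitious=surrept == "1",
                    protocol=_parse_enum(Protocol, protocol, path, line),
                    focal_id=focal_id,
                    event_id=event_id,
                )
            except InvariantError as exc:
                raise InvariantError(f"{path}:{line}: {exc}") from exc
            out.append(event)
    return out


def write_events(path: str | Path, events: Iterable[BehaviourEvent]) -> None:
    with _open_writer(path) as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_EVENTS_HEADER)
        for ev in events:
            duration = "" if ev.duration_s is None else format(ev.duration_s, "g")
            writer.writerow(
                [
                    ev.event_id,
                    ev.type.value,
                    ev.actor,
                    ev.recipient,
                    ev.time.day,
                    ev.time.clock,
                    duration,
                    "1" if ev.surreptitious else "0",
                    ev.protocol.value,
                    ev.focal_id,
                ]
            )


def read_states(
    path: str | Path, roster: Sequence[Individual]
) -> dict[str, dict[int, ReproductiveState]]:
    """Daily reproductive-state series as female -> {day -> state}."""
    path = Path(path)
    females = {ind.id for ind in roster if ind.sex is Sex.FEMALE}
    out: dict[str, dict[int, ReproductiveState]] = {}
    with _open_reader(path) as fh:
        reader = csv.reader(fh)
        _check_header(next(reader, None), _STATES_HEADER, path)
        for line, row in enumerate(reader, start=2):
            if len(row) != 3:
                raise SchemaError(f"{path}:{line}: expected 3 fields, got {len(row)}")
            female, day, state = row
            if female not in females:
                raise RecordLinkError(f"{path}:{line}: unknown female {female!r}")
            series = out.setdefault(female, {})
            d = int(day)
            if d in series:
                raise SchemaError(f"{path}:{line}: duplicate day {d} for {female}")
            series[d] = _parse_enum(ReproductiveState, state, path, line)
    return out


def write_states(
    path: str | Path, states: Mapping[str, Mapping[int, ReproductiveState]]
) -> None:
    with _open_writer(path) as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_STATES_HEADER)
        for female in sorted(states):
            series = states[female]
            for day in sorted(series):
                writer.writerow([female, day, series[day].value])


def assemble_focals(
    scans: Sequence[ScanRecord],
    events: Sequence[BehaviourEvent],
    states: Mapping[str, Mapping[int, ReproductiveState]],
) -> list[FocalSample]:
    """Rebuild focal samples from flat tables using the focal_id link column.

    Scans/events without a focal_id (the ad libitum stream) are ignored here.
    """
    scans_by_focal: dict[str, list[ScanRecord]] = {}
    for scan in scans:
        if scan.focal_id:
            scans_by_focal.setdefault(scan.focal_id, []).append(scan)
    events_by_focal: dict[str, list[BehaviourEvent]] = {}
    for ev in events:
        if ev.focal_id:
            events_by_focal.setdefault(ev.focal_id, []).append(ev)

    out: list[FocalSample] = []
    for focal_id in sorted(scans_by_focal):
        group = sorted(scans_by_focal[focal_id], key=lambda s: s.time)
        female = group[0].focal_female
        start = group[0].time
        state = states.get(female, {}).get(start.day)
        if state is None:
            raise RecordLinkError(
                f"no reproductive state recorded for {female} on day {start.day}"
            )
        out.append(
            FocalSample(
                focal_id=focal_id,
                focal_female=female,
                start_time=start,
                state=state,
                scans=tuple(group),
                events=tuple(sorted(events_by_focal.get(focal_id, []), key=lambda e: e.time)),
            )
        )
    return out
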