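"""Domain types and CSV I/O for land-based observation records.

A survey session is a daily observation shift during which dolphin groups
are followed continuously once sighted.  The atomic datum is a per-minute
*tick*: one :class:`ObservationRecord` holding the behavioral state of the
focal group, whether a vessel is within the proximity radius (a boolean
judged in the field, conventionally ~200 m), and the group's reaction to
that vessel.

The behavioral state space is the four-state ethogram used in coastal
delphinid scan-sampling studies:

=====  ==================================================================
code   behavior
=====  ==================================================================
FEE    feeding activities (frequent direction changes, variable dives)
TRA    traveling (consistent direction)
SOC    socializing (physical contact, synchronized movement, short dives)
RES    resting (clustered at the surface, constant direction)
=====  ==================================================================

``RES`` is a legal input everywhere even if a particular survey never
records it.  Reactions to a nearby vessel are ``POS`` (approach /
bowriding), ``NEU`` (behavior maintained), ``NEG`` (behavior disrupted,
formation change, longer dives, tailslaps); ``NONE`` is reserved for
ticks with no vessel within the radius.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "BehaviorState",
    "ReactionType",
    "ObservationRecord",
    "SampleBlock",
    "Event",
    "SchemaError",
    "RecordValidationError",
    "CSV_COLUMNS",
    "STATE_ORDER",
    "read_records",
    "write_records",
    "sighting_fraction",
]


class BehaviorState(str, enum.Enum):
    """Behavioral state of a dolphin group (four-state ethogram)."""

    FEE = "FEE"
    TRA = "TRA"
    SOC = "SOC"
    RES = "RES"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ReactionType(str, enum.Enum):
    """Reaction of the group to a vessel within the proximity radius."""

    POS = "POS"
    NEU = "NEU"
    NEG = "NEG"
    NONE = "NONE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical ordering of the state space, used for matrices and tables.
STATE_ORDER: tuple[BehaviorState, ...] = (
    BehaviorState.FEE,
    BehaviorState.TRA,
    BehaviorState.SOC,
    BehaviorState.RES,
)

#: Severity ordering used to break ties conservatively when aggregating
#: tick reactions into a block reaction (most disruptive wins).
REACTION_SEVERITY: dict[ReactionType, int] = {
    ReactionType.NEG: 2,
    ReactionType.NEU: 1,
    ReactionType.POS: 0,
}

#: Canonical CSV column order for observation records.
CSV_COLUMNS: tuple[str, ...] = (
    "session_id",
    "timestamp_min",
    "group_id",
    "state",
    "vessel_present",
    "reaction",
)


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class RecordValidationError(ValueError):
    """A row violates a domain invariant.

    Attributes
    ----------
    row : int or None
        1-based file row (header = row 1) of the offending record, when
        the error arose while parsing a file.
    """

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"row {row}: {message}")
        self.row = row


@dataclass(frozen=True, order=True)
class ObservationRecord:
    """One per-minute tick of continuous group sampling.

    ``timestamp_min`` counts integer minutes since the start of the
    session; no calendar dates are needed for any statistic downstream.
    ``vessel_present`` is the field judgment "vessel within the proximity
    radius"; the package never computes distances.
    """

    session_id: str
    group_id: str
    timestamp_min: int
    state: BehaviorState
    vessel_present: bool
    reaction: ReactionType

    def __post_init__(self) -> None:
        object.__setattr__(self, "state", BehaviorState(self.state))
        object.__setattr__(self, "reaction", ReactionType(self.reaction))
        if self.timestamp_min < 0:
            raise RecordValidationError(
                f"timestamp_min must be >= 0, got {self.timestamp_min}"
            )
        if not self.vessel_present and self.reaction is not ReactionType.NONE:
            raise RecordValidationError(
                "reaction must be NONE when vessel_present is false "
                f"(got {self.reaction.value})"
            )


@dataclass
class SampleBlock:
    """One 5-min (or truncated) sampling block for a dolphin group.

    ``state`` is the dominant (modal) behavioral state of the block's
    ticks, ``duration`` its true length in minutes (the final block of a
    sighting may be shorter than the nominal block length).
    """

    session_id: str
    group_id: str
    block_index: int
    start: int
    duration: int
    state: BehaviorState
    vessel_present: bool
    reaction: ReactionType
    event_id: str | None = None

    @property
    def end(self) -> int:
        return self.start + self.duration


@dataclass
class Event:
    """A continuous sighting of one group: the unit of independence.

    Events are separated from other events of the same session by at
    least the independence interval (15 min by default), and are the
    clustering unit for every statistic in the pipeline.
    """

    event_id: str
    session_id: str
    group_id: str
    blocks: list[SampleBlock]

    @property
    def total_minutes(self) -> int:
        return sum(b.duration for b in self.blocks)

    @property
    def start(self) -> int:
        return self.blocks[0].start

    @property
    def end(self) -> int:
        return self.blocks[-1].end


_TRUTHY = {"1", "true", "True", "TRUE"}
_FALSY = {"0", "false", "False", "FALSE"}


def read_records(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[ObservationRecord]:
    """Read observation records from a CSV file.

    Parameters
    ----------
    path : path
        CSV file with the canonical columns (see :data:`CSV_COLUMNS`).
    schema : mapping, optional
        Maps canonical column names to the names used in the file, for
        ingesting third-party exports.

    Returns
    -------
    list of ObservationRecord, sorted by (session, group, timestamp).

    Raises
    ------
    SchemaError
        If a required column is absent (the message names it).
    RecordValidationError
        If a row carries an unknown state/reaction code, a malformed
        timestamp or vessel flag, a reaction without a vessel, or if
        timestamps are not strictly increasing within (session, group).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {}
    for canonical in CSV_COLUMNS:
        actual = schema.get(canonical, canonical) if schema else canonical
        if actual not in df.columns:
            raise SchemaError(f"missing required column: {actual!r}")
        rename[actual] = canonical
    df = df.rename(columns=rename)

    records: list[ObservationRecord] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        file_row = pos + 2  # 1-based, after the header
        try:
            ts = int(row.timestamp_min)
        except ValueError:
            raise RecordValidationError(
                f"bad timestamp_min {row.timestamp_min!r}", row=file_row
            ) from None
        raw_vessel = str(row.vessel_present)
        if raw_vessel in _TRUTHY:
            vessel = True
        elif raw_vessel in _FALSY:
            vessel = False
        else:
            raise RecordValidationError(
                f"bad vessel_present {raw_vessel!r}", row=file_row
            )
        try:
            record = ObservationRecord(
                session_id=str(row.session_id),
                group_id=str(row.group_id),
                timestamp_min=ts,
                state=BehaviorState(row.state),
                vessel_present=vessel,
                reaction=ReactionType(row.reaction),
            )
        except ValueError as exc:
            raise RecordValidationError(str(exc), row=file_row) from None
        records.append(record)

    records.sort(key=lambda r: (r.session_id, r.group_id, r.timestamp_min))
    _check_monotone(records)
    return records


def _check_monotone(records: Sequence[ObservationRecord]) -> None:
    for prev, cur in zip(records, records[1:]):
        same_stream = (
            prev.session_id == cur.session_id and prev.group_id == cur.group_id
        )
        if same_stream and cur.timestamp_min <= prev.timestamp_min:
            raise RecordValidationError(
                "timestamps must be strictly increasing within "
                f"(session {cur.session_id!r}, group {cur.group_id!r}): "
                f"{prev.timestamp_min} then {cur.timestamp_min}"
            )


def write_records(
    records: Iterable[ObservationRecord], path: str | Path
) -> Path:
    """Write records to CSV in the canonical dialect.

    Comma-separated, UTF-8, header row, columns in :data:`CSV_COLUMNS`
    order, ``vessel_present`` as 0/1, rows sorted by (session, group,
    timestamp).  Reading the result back yields the same records, and
    writing again is byte-identical (canonicalization is idempotent).
    """
    path = Path(path)
    rows = sorted(records, key=lambda r: (r.session_id, r.group_id, r.timestamp_min))
    df = pd.DataFrame(
        {
            "session_id": [r.session_id for r in rows],
            "timestamp_min": [r.timestamp_min for r in rows],
            "group_id": [r.group_id for r in rows],
            "state": [r.state.value for r in rows],
            "vessel_present": [int(r.vessel_present) for r in rows],
            "reaction": [r.reaction.value for r in rows],
        },
        columns=list(CSV_COLUMNS),
    )
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def sighting_fraction(total_effort_hours: float, sighted_hours: float) -> float:
    """Percentage of survey effort during which dolphins were in sight.

    Parameters
    ----------
    total_effort_hours : float
        Total observation effort, in hours; must be positive.
    sighted_hours : float
        Hours with a dolphin group in sight; must lie in
        ``[0, total_effort_hours]``.

    Returns
    -------
    float
        ``100 * sighted_hours / total_effort_hours``.
    """
    if total_effort_hours <= 0:
        raise ValueError(
            f"total_effort_hours must be > 0, got {total_effort_hours}"
        )
    if sighted_hours < 0 or sighted_hours > total_effort_hours:
        raise ValueError(
            "sighted_hours must lie in [0, total_effort_hours], got "
            f"{sighted_hours}"
        )
    return 100.0 * sighted_hours / total_effort_hours
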