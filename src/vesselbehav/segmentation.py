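"""Dominant-state block construction and independence-based event segmentation.

Raw per-minute records become 5-min :class:`~vesselbehav.obs_model.SampleBlock`
objects carrying a single dominant state, then maximal runs of blocks are
grouped into :class:`~vesselbehav.obs_model.Event` objects: two sighting
runs of the same (session, group) stream belong to the same event iff the
gap between them is strictly less than the independence interval (15 min);
a gap of 15 min or more starts a new event.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

from .obs_model import (
    REACTION_SEVERITY,
    BehaviorState,
    Event,
    ObservationRecord,
    ReactionType,
    SampleBlock,
)

__all__ = ["dominant_state", "make_blocks", "segment_events"]

BLOCK_MINUTES = 5
INDEPENDENCE_MINUTES = 15


def dominant_state(
    ticks: Sequence[tuple[int, BehaviorState]]
) -> BehaviorState:
    """Modal behavioral state of the ticks within one sampling block.

    Ties are broken by the state occupying the latest tick in the block,
    which is deterministic and independent of label alphabet.

    Parameters
    ----------
    ticks : sequence of (timestamp, state)

    Raises
    ------
    ValueError
        On an empty tick list.
    """
    if not ticks:
        raise ValueError("dominant_state requires at least one tick")
    counts = Counter(BehaviorState(s) for _, s in ticks)
    top = max(counts.values())
    tied = {s for s, c in counts.items() if c == top}
    if len(tied) == 1:
        return next(iter(tied))
    for _, state in sorted(ticks, key=lambda t: t[0], reverse=True):
        if BehaviorState(state) in tied:
            return BehaviorState(state)
    raise AssertionError("unreachable")  # pragma: no cover


def _block_reaction(
    reactions: Iterable[ReactionType], vessel_present: bool
) -> ReactionType:
    """Aggregate tick reactions into one block reaction.

    Modal non-NONE reaction; ties go to the most disruptive category
    (NEG > NEU > POS), the conservative choice for impact detection.
    NONE if no vessel was present (or no reaction was recorded).
    """
    if not vessel_present:
        return ReactionType.NONE
    counts = Counter(r for r in reactions if r is not ReactionType.NONE)
    if not counts:
        return ReactionType.NONE
    top = max(counts.values())
    tied = [r for r, c in counts.items() if c == top]
    return max(tied, key=lambda r: REACTION_SEVERITY[r])


def make_blocks(
    records: Sequence[ObservationRecord],
    block_minutes: int = BLOCK_MINUTES,
    tick_minutes: int = 1,
) -> list[SampleBlock]:
    """Tile continuous sightings into dominant-state sampling blocks.

    Records are grouped into (session, group) streams; a stream breaks
    into continuous runs wherever consecutive timestamps differ by more
    than one tick.  Each run is tiled with blocks of ``block_minutes``
    from its first tick; the final block may be truncated.  Block
    attributes are aggregated from the ticks:

    * ``state`` — the dominant (modal) state, latest-tick tie-break;
    * ``vessel_present`` — true if *any* tick has a vessel within the
      radius (conservative exposure definition, configurable upstream);
    * ``reaction`` — modal non-NONE tick reaction, ties to the most
      negative category; NONE whenever the block is vessel-absent.

    Input must already be sorted by (session, group, timestamp), as
    produced by :func:`~vesselbehav.obs_model.read_records`.
    """
    if block_minutes <= 0 or tick_minutes <= 0:
        raise ValueError("block_minutes and tick_minutes must be positive")
    ticks_per_block = block_minutes // tick_minutes
    if ticks_per_block < 1:
        raise ValueError("block_minutes must be >= tick_minutes")

    key = lambda r: (r.session_id, r.group_id, r.timestamp_min)
    if any(key(a) > key(b) for a, b in zip(records, records[1:])):
        raise ValueError("records must be sorted by (session, group, timestamp)")

    blocks: list[SampleBlock] = []
    run: list[ObservationRecord] = []

    def flush(run: list[ObservationRecord]) -> None:
        if not run:
            return
        for index in range(0, len(run), ticks_per_block):
            chunk = run[index : index + ticks_per_block]
            vessel = any(r.vessel_present for r in chunk)
            blocks.append(
                SampleBlock(
                    session_id=chunk[0].session_id,
                    group_id=chunk[0].group_id,
                    block_index=index // ticks_per_block,
                    start=chunk[0].timestamp_min,
                    duration=len(chunk) * tick_minutes,
                    state=dominant_state(
                        [(r.timestamp_min, r.state) for r in chunk]
                    ),
                    vessel_present=vessel,
                    reaction=_block_reaction((r.reaction for r in chunk), vessel),
                )
            )

    for record in records:
        if run and (
            record.session_id != run[-1].session_id
            or record.group_id != run[-1].group_id
            or record.timestamp_min - run[-1].timestamp_min > tick_minutes
        ):
            flush(run)
            run = []
        run.append(record)
    flush(run)
    return blocks


def segment_events(
    blocks: Sequence[SampleBlock],
    independence_minutes: int = INDEPENDENCE_MINUTES,
) -> list[Event]:
    """Group sampling blocks into independence-respecting events.

    Within one (session, group) stream, consecutive runs separated by a
    gap strictly below ``independence_minutes`` merge into a single
    event; a gap of ``independence_minutes`` or more starts a new event.
    Events never span sessions or groups.  Block indices are rewritten
    to be contiguous within each event and ``event_id`` is stamped onto
    every block, so re-segmenting segmented blocks is the identity.

    Blocks must be sorted by (session, group, start).
    """
    key = lambda b: (b.session_id, b.group_id, b.start)
    if any(key(a) > key(b) for a, b in zip(blocks, blocks[1:])):
        raise ValueError("blocks must be sorted by (session, group, start)")

    events: list[Event] = []
    current: list[SampleBlock] = []

    def close(current: list[SampleBlock]) -> None:
        if not current:
            return
        event_id = f"E{len(events) + 1:04d}"
        for i, b in enumerate(current):
            b.event_id = event_id
            b.block_index = i
        events.append(
            Event(
                event_id=event_id,
                session_id=current[0].session_id,
                group_id=current[0].group_id,
                blocks=list(current),
            )
        )

    for block in blocks:
        if current:
            prev = current[-1]
            same_stream = (
                block.session_id == prev.session_id
                and block.group_id == prev.group_id
            )
            gap = block.start - prev.end
            if not same_stream or gap >= independence_minutes:
                close(current)
                current = []
        current.append(block)
    close(current)
    return events
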