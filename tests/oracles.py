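"""Independent brute-force oracles used to validate the pipeline stages.

Everything here is deliberately naive — plain dict/loop re-implementations
that share no code with the package — so that agreement with the library
is a meaningful check rather than a tautology.
"""

from collections import Counter, defaultdict


def oracle_blocks(records, block_minutes=5, tick_minutes=1):
    """Index-arithmetic tiling of tick streams into blocks.

    Returns a list of dicts with session/group/start/duration/state/
    vessel/reaction per block, in (session, group, start) order.
    """
    streams = defaultdict(list)
    for r in records:
        streams[(r.session_id, r.group_id)].append(r)
    out = []
    for key in sorted(streams):
        ticks = sorted(streams[key], key=lambda r: r.timestamp_min)
        runs, cur = [], [ticks[0]]
        for prev, r in zip(ticks, ticks[1:]):
            if r.timestamp_min - prev.timestamp_min > tick_minutes:
                runs.append(cur)
                cur = []
            cur.append(r)
        runs.append(cur)
        per_block = block_minutes // tick_minutes
        for run in runs:
            for i in range(0, len(run), per_block):
                chunk = run[i : i + per_block]
                vessel = any(r.vessel_present for r in chunk)
                out.append(
                    {
                        "session": key[0],
                        "group": key[1],
                        "start": chunk[0].timestamp_min,
                        "duration": len(chunk) * tick_minutes,
                        "state": oracle_mode(
                            [(r.timestamp_min, r.state.value) for r in chunk]
                        ),
                        "vessel": vessel,
                        "reaction": oracle_block_reaction(chunk, vessel),
                    }
                )
    return out


def oracle_mode(ticks):
    """Exhaustive mode count; ties to the state holding the latest tick."""
    counts = Counter(s for _, s in ticks)
    best = max(counts.values())
    tied = [s for s in counts if counts[s] == best]
    latest = {}
    for t, s in ticks:
        latest[s] = max(latest.get(s, -1), t)
    return max(tied, key=lambda s: latest[s])


def oracle_block_reaction(chunk, vessel):
    if not vessel:
        return "NONE"
    counts = Counter(r.reaction.value for r in chunk if r.reaction.value != "NONE")
    if not counts:
        return "NONE"
    best = max(counts.values())
    tied = [r for r in counts if counts[r] == best]
    severity = {"NEG": 2, "NEU": 1, "POS": 0}
    return max(tied, key=lambda r: severity[r])


def oracle_events(oblocks, independence_minutes=15):
    """Linear scan over oracle blocks: lists of block indices per event."""
    events = []
    cur = []
    for idx, b in enumerate(oblocks):
        if cur:
            prev = oblocks[cur[-1]]
            same = (
                b["session"] == prev["session"] and b["group"] == prev["group"]
            )
            gap = b["start"] - (prev["start"] + prev["duration"])
            if not same or gap >= independence_minutes:
                events.append(cur)
                cur = []
        cur.append(idx)
    if cur:
        events.append(cur)
    return events


def oracle_budget(oblocks, event_ids, scenario):
    """Per-state minute tallies for a scenario over oracle blocks."""
    minutes = defaultdict(float)
    for b in oblocks:
        if scenario == "ABSENT" and b["vessel"]:
            continue
        if scenario == "PRESENT" and not b["vessel"]:
            continue
        minutes[b["state"]] += b["duration"]
    return dict(minutes)


def oracle_reaction_sums(oblocks, event_of_block):
    """Sum vessel-present minutes by (event, state, reaction)."""
    sums = defaultdict(float)
    for idx, b in enumerate(oblocks):
        if b["vessel"] and b["reaction"] != "NONE":
            sums[(event_of_block[idx], b["state"], b["reaction"])] += b["duration"]
    return {k: v for k, v in sums.items() if v > 0}


def oracle_transition_counts(oblocks, events, rule):
    """Pairwise scan over consecutive blocks of each event."""
    control = defaultdict(int)
    impact = defaultdict(int)
    for member_indices in events:
        for a_idx, b_idx in zip(member_indices, member_indices[1:]):
            a, b = oblocks[a_idx], oblocks[b_idx]
            if rule == "preceding":
                is_impact = a["vessel"]
            elif rule == "succeeding":
                is_impact = b["vessel"]
            else:
                is_impact = a["vessel"] and b["vessel"]
            target = impact if is_impact else control
            target[(a["state"], b["state"])] += 1
    return dict(control), dict(impact)
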