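"""Control/impact first-order Markov chains over dominant-state blocks.

Within each event, every ordered pair of consecutive blocks contributes
one behavioral transition i -> j; transitions never cross event
boundaries.  Each transition is assigned to the CONTROL (no vessel) or
IMPACT (vessel within the proximity radius) chain by an *exposure rule*,
and row-normalized counts give the maximum-likelihood transition
probabilities

    p_ij = a_ij / sum_j a_ij,

where ``a_ij`` is the number of observed i -> j transitions.  Rows that
were never left from (zero support) are reported as "no data" (NaN),
never as fabricated absorbing states.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .obs_model import STATE_ORDER, Event

__all__ = [
    "EXPOSURE_RULES",
    "TransitionCounts",
    "TransitionMatrix",
    "ChainComparison",
    "collect_transitions",
    "count_transitions",
    "transition_probabilities",
    "compare_chains",
    "export_chain_diagram",
]

_STATES = [s.value for s in STATE_ORDER]
_INDEX = {s: i for i, s in enumerate(_STATES)}
_N = len(_STATES)

#: How a transition spanning a vessel arrival/departure is assigned:
#: ``preceding`` — IMPACT iff the earlier block is vessel-present (the
#: behavioral response follows the stimulus; the default), ``succeeding``
#: — IMPACT iff the later block is, ``both`` — IMPACT iff both are.
#: Every rule assigns each transition to exactly one scenario, so
#: CONTROL + IMPACT counts always equal the total consecutive pairs.
EXPOSURE_RULES = ("preceding", "succeeding", "both")


@dataclass
class TransitionCounts:
    """Integer transition counts a_ij for one scenario."""

    scenario: str
    a: np.ndarray  # (4, 4) int
    exposure_rule: str = "preceding"

    @property
    def n_transitions(self) -> int:
        return int(self.a.sum())

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.a, index=_STATES, columns=_STATES)


@dataclass
class TransitionMatrix:
    """Row-stochastic transition probabilities for one scenario.

    ``p[i, j]`` is NaN for every j when state i has zero row support:
    an unobserved row is "no data", not a zero-probability row.
    """

    scenario: str
    p: np.ndarray  # (4, 4) float, NaN rows where unsupported
    row_support: np.ndarray  # (4,) int
    exposure_rule: str = "preceding"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p, index=_STATES, columns=_STATES)


@dataclass
class ChainComparison:
    """Per-cell impact-minus-control differences with optional permutation p."""

    diff: np.ndarray  # (4, 4) float, NaN where either chain lacks support
    p_values: np.ndarray | None
    n_permutations: int
    seed: int | None
    exposure_rule: str


def collect_transitions(
    events: Sequence[Event], exposure_rule: str = "preceding"
) -> pd.DataFrame:
    """One row per within-event consecutive block pair.

    Columns: ``event_id``, ``from_state``, ``to_state``, ``impact``
    (bool, per the exposure rule).  Events with fewer than two blocks
    contribute nothing.
    """
    if exposure_rule not in EXPOSURE_RULES:
        raise ValueError(
            f"exposure_rule must be one of {EXPOSURE_RULES}, got {exposure_rule!r}"
        )
    rows = []
    for event in events:
        for earlier, later in zip(event.blocks, event.blocks[1:]):
            if exposure_rule == "preceding":
                impact = earlier.vessel_present
            elif exposure_rule == "succeeding":
                impact = later.vessel_present
            else:  # both
                impact = earlier.vessel_present and later.vessel_present
            rows.append(
                (event.event_id, earlier.state.value, later.state.value, impact)
            )
    return pd.DataFrame(
        rows, columns=["event_id", "from_state", "to_state", "impact"]
    )


def _count_matrix(frame: pd.DataFrame) -> np.ndarray:
    a = np.zeros((_N, _N), dtype=int)
    if len(frame):
        i = frame["from_state"].map(_INDEX).to_numpy()
        j = frame["to_state"].map(_INDEX).to_numpy()
        np.add.at(a, (i, j), 1)
    return a


def count_transitions(
    events: Sequence[Event], exposure_rule: str = "preceding"
) -> tuple[TransitionCounts, TransitionCounts]:
    """Tally transitions into (CONTROL, IMPACT) count matrices."""
    frame = collect_transitions(events, exposure_rule)
    control = TransitionCounts(
        "CONTROL", _count_matrix(frame[~frame["impact"]]), exposure_rule
    )
    impact = TransitionCounts(
        "IMPACT", _count_matrix(frame[frame["impact"]]), exposure_rule
    )
    return control, impact


def transition_probabilities(counts: TransitionCounts) -> TransitionMatrix:
    """Row-normalize counts; zero-support rows become NaN ("no data")."""
    a = np.asarray(counts.a, dtype=float)
    support = a.sum(axis=1)
    p = np.full_like(a, np.nan)
    for i in range(_N):
        if support[i] > 0:
            p[i] = a[i] / support[i]
    return TransitionMatrix(
        scenario=counts.scenario,
        p=p,
        row_support=support.astype(int),
        exposure_rule=counts.exposure_rule,
    )


def _diff_from_labels(
    cells: np.ndarray, impact_labels: np.ndarray
) -> np.ndarray:
    """Impact-minus-control probability difference from flat cell codes."""
    counts_impact = np.bincount(cells[impact_labels], minlength=_N * _N).reshape(
        _N, _N
    )
    counts_control = np.bincount(
        cells[~impact_labels], minlength=_N * _N
    ).reshape(_N, _N)
    with np.errstate(invalid="ignore"):
        p_i = counts_impact / counts_impact.sum(axis=1, keepdims=True)
        p_c = counts_control / counts_control.sum(axis=1, keepdims=True)
    return p_i - p_c


def compare_chains(
    control: TransitionMatrix,
    impact: TransitionMatrix,
    transitions: pd.DataFrame | None = None,
    n_permutations: int = 0,
    seed: int | None = None,
) -> ChainComparison:
    """Per-cell chain differences, optionally with permutation p-values.

    The null distribution is built by shuffling the CONTROL/IMPACT
    labels over transitions *within each event* (preserving each event's
    label counts), re-estimating both chains, and recording the absolute
    cell difference; the two-sided p-value per cell is the add-one
    permutation estimate.  ``transitions`` is the frame from
    :func:`collect_transitions` and is required when
    ``n_permutations > 0``.  Cells whose row lacks support in either
    observed chain carry NaN differences and p-values.
    """
    if control.exposure_rule != impact.exposure_rule:
        raise ValueError("chains were built under different exposure rules")
    diff = impact.p - control.p
    if n_permutations <= 0:
        return ChainComparison(diff, None, 0, seed, control.exposure_rule)
    if transitions is None or transitions.empty:
        raise ValueError("permutation test requires the collected transitions")

    frame = transitions.sort_values("event_id", kind="stable")
    ev = pd.factorize(frame["event_id"])[0]
    cells = (
        frame["from_state"].map(_INDEX).to_numpy() * _N
        + frame["to_state"].map(_INDEX).to_numpy()
    )
    labels = frame["impact"].to_numpy(dtype=bool)

    observed = _diff_from_labels(cells, labels)
    rng = np.random.default_rng(seed)
    exceed = np.zeros((_N, _N), dtype=int)
    valid = np.zeros((_N, _N), dtype=int)
    obs_abs = np.abs(observed)
    n = len(cells)
    for _ in range(n_permutations):
        order = np.lexsort((rng.random(n), ev))  # within-event shuffle
        perm_diff = _diff_from_labels(cells, labels[order])
        with np.errstate(invalid="ignore"):
            hit = np.abs(perm_diff) >= obs_abs - 1e-12
        ok = ~np.isnan(perm_diff) & ~np.isnan(observed)
        exceed += np.where(ok & hit, 1, 0)
        valid += np.where(ok, 1, 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        p_values = (exceed + 1.0) / (valid + 1.0)
    p_values[np.isnan(observed)] = np.nan
    # p is only meaningful where the observed difference is defined
    p_values[np.isnan(diff)] = np.nan
    return ChainComparison(
        diff, p_values, n_permutations, seed, control.exposure_rule
    )


def export_chain_diagram(matrix: TransitionMatrix, path: str | Path) -> Path:
    """Write the chain as a DOT digraph (nodes = states, edges = p_ij > 0).

    Edge labels carry probabilities rounded to 2 decimals, the usual
    rendering precision for behavioral transition diagrams; zero-support
    rows become annotated nodes with no out-edges.
    """
    path = Path(path)
    lines = [f'digraph "{matrix.scenario}" {{', "  rankdir=LR;"]
    for i, state in enumerate(_STATES):
        if matrix.row_support[i] == 0:
            lines.append(f'  {state} [label="{state}\\n(no data)"];')
        else:
            lines.append(f'  {state} [label="{state}"];')
    for i, src in enumerate(_STATES):
        if matrix.row_support[i] == 0:
            continue
        for j, dst in enumerate(_STATES):
            p = matrix.p[i, j]
            if p > 0:
                lines.append(f'  {src} -> {dst} [label="{p:.2f}"];')
    lines.append("}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
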