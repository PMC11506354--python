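"""Activity budgets per vessel scenario and nonparametric comparisons.

"Time spent" in a state is accumulated per event from block durations
(truncated blocks contribute their true minutes, not a nominal 5), split
by vessel scenario: ABSENT (no vessel within the radius), PRESENT, or
ALL.  Scenario comparisons follow the standard nonparametric route for
such data: Shapiro–Wilk and Levene checks are computed for the record,
and the hypothesis test is a two-sided Mann–Whitney U on per-event sums
regardless of their outcome.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .obs_model import STATE_ORDER, BehaviorState, Event, SampleBlock

__all__ = [
    "Scenario",
    "BudgetTable",
    "TestResult",
    "TimeSummary",
    "activity_budget",
    "exclude_rare_states",
    "normality_checks",
    "compare_budgets",
    "time_in_area_summary",
    "EXACT_MW_MAX_N",
]

#: Largest pooled sample size for which the Mann–Whitney p-value is
#: computed by exhaustive enumeration of group assignments.
EXACT_MW_MAX_N = 12


class Scenario(str, enum.Enum):
    ABSENT = "ABSENT"
    PRESENT = "PRESENT"
    ALL = "ALL"


def _scenario_blocks(event: Event, scenario: Scenario) -> list[SampleBlock]:
    if scenario is Scenario.ALL:
        return list(event.blocks)
    want = scenario is Scenario.PRESENT
    return [b for b in event.blocks if b.vessel_present == want]


@dataclass
class TestResult:
    """A named test statistic with its p-value and group sizes."""

    statistic_name: str
    statistic: float
    p_value: float
    n1: int
    n2: int = 0
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")


@dataclass
class BudgetTable:
    """Per-scenario activity budget.

    ``per_state`` has one row per behavioral state with the summed
    minutes, the percent of the scenario total, and the block count;
    ``per_event`` is an event × state table of minutes, the input to the
    scenario comparisons.  Percentages always sum to 100 over states
    (up to float error) when any time was observed.
    """

    scenario: Scenario
    per_state: pd.DataFrame
    per_event: pd.DataFrame
    total_minutes: float
    empty: bool = False

    def percent(self, state: BehaviorState | str) -> float:
        code = BehaviorState(state).value
        return float(self.per_state.loc[code, "percent"])


def activity_budget(
    events: Sequence[Event], scenario: Scenario | str = Scenario.ALL
) -> BudgetTable:
    """Summed time per behavioral state under one vessel scenario.

    Blocks are filtered by the scenario's vessel flag, durations are
    summed per (event, state), and percentages are taken over the
    scenario's total minutes.  An empty selection yields a zero-total
    table with ``empty=True`` (and a warning) rather than an error.
    """
    if not events:
        raise ValueError("activity_budget requires at least one event")
    scenario = Scenario(scenario)
    codes = [s.value for s in STATE_ORDER]

    rows = []
    for event in events:
        for b in _scenario_blocks(event, scenario):
            rows.append((event.event_id, b.state.value, b.duration))
    if rows:
        df = pd.DataFrame(rows, columns=["event_id", "state", "minutes"])
        per_event = (
            df.pivot_table(
                index="event_id",
                columns="state",
                values="minutes",
                aggfunc="sum",
                fill_value=0.0,
            )
            .reindex(columns=codes, fill_value=0.0)
            .astype(float)
        )
        minutes = df.groupby("state")["minutes"].sum().reindex(codes, fill_value=0.0)
        n_blocks = df.groupby("state").size().reindex(codes, fill_value=0)
    else:
        warnings.warn(f"no blocks match scenario {scenario.value}", stacklevel=2)
        per_event = pd.DataFrame(columns=codes, dtype=float)
        minutes = pd.Series(0.0, index=codes)
        n_blocks = pd.Series(0, index=codes)

    total = float(minutes.sum())
    percent = 100.0 * minutes / total if total > 0 else minutes * 0.0
    per_state = pd.DataFrame(
        {
            "minutes": minutes.astype(float),
            "percent": percent.astype(float),
            "n_blocks": n_blocks.astype(int),
        }
    )
    per_state.index.name = "state"
    return BudgetTable(
        scenario=scenario,
        per_state=per_state,
        per_event=per_event,
        total_minutes=total,
        empty=total == 0,
    )


def exclude_rare_states(
    events: Sequence[Event], min_samples: int = 12
) -> tuple[list[SampleBlock], dict]:
    """Flag states too sparsely observed for hypothesis testing.

    States with fewer than ``min_samples`` blocks over the whole survey
    are excluded from inferential analyses (never from descriptive
    budgets).  Returns the retained blocks and a report mapping each
    state to its block count under ``"kept"`` / ``"excluded"``.
    """
    counts = {s.value: 0 for s in STATE_ORDER}
    blocks: list[SampleBlock] = []
    for event in events:
        for b in event.blocks:
            counts[b.state.value] += 1
            blocks.append(b)
    excluded = {s: c for s, c in counts.items() if c < min_samples}
    kept_blocks = [b for b in blocks if b.state.value not in excluded]
    report = {
        "min_samples": min_samples,
        "excluded": excluded,
        "kept": {s: c for s, c in counts.items() if s not in excluded},
    }
    return kept_blocks, report


def normality_checks(
    *samples: Sequence[float], names: Sequence[str] | None = None
) -> tuple[list[TestResult], TestResult]:
    """Shapiro–Wilk per sample and Levene across samples.

    These are reported for the record only; the pipeline compares
    scenarios nonparametrically regardless of their outcome.  Requires
    n >= 3 in each sample for Shapiro and >= 2 samples for Levene.
    """
    if len(samples) < 2:
        raise ValueError("normality_checks requires at least 2 samples for Levene")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if names is None:
        names = [f"sample{i + 1}" for i in range(len(arrays))]
    shapiros: list[TestResult] = []
    for name, arr in zip(names, arrays):
        if arr.size < 3:
            raise ValueError(
                f"Shapiro–Wilk needs n >= 3, got n={arr.size} for {name}"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = stats.shapiro(arr)
        shapiros.append(
            TestResult(f"shapiro[{name}]", float(stat), float(p), n1=arr.size)
        )
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:  # all values identical: zero spread everywhere
        levene = TestResult(
            "levene", 0.0, 1.0, n1=arrays[0].size, n2=arrays[1].size,
            note="all values identical",
        )
    else:
        stat, p = stats.levene(*arrays)
        levene = TestResult(
            "levene", float(stat), float(p), n1=arrays[0].size, n2=arrays[1].size
        )
    return shapiros, levene


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann–Whitney U for the first sample, ties counted half."""
    greater = (x[:, None] > y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    return float(greater) + 0.5 * float(ties)


def _exact_mw_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p by exhaustive enumeration of group assignments.

    Under the exchangeable null every split of the pooled values into
    groups of sizes (n1, n2) is equally likely.  The two-sided p-value
    follows the standard convention of twice the smaller one-sided tail
    probability, clipped at 1 (with ties the permutation distribution of
    U need not be symmetric, so the two tails are counted separately).
    """
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    u_obs = _u_statistic(x, y)
    ge = le = total = 0
    indices = set(range(n))
    for combo in combinations(range(n), n1):
        xs = pooled[list(combo)]
        ys = pooled[list(indices - set(combo))]
        u = _u_statistic(xs, ys)
        ge += u >= u_obs - 1e-12
        le += u <= u_obs + 1e-12
        total += 1
    return min(1.0, 2.0 * min(ge, le) / total)


def compare_budgets(
    sums_absent: Sequence[float], sums_present: Sequence[float]
) -> TestResult:
    """Two-sided Mann–Whitney U between per-event scenario sums.

    Exact enumeration over all group assignments when the pooled sample
    size is at most :data:`EXACT_MW_MAX_N`; otherwise the normal
    approximation with tie and continuity corrections.  The reported U
    is the statistic of the first sample.
    """
    x = np.asarray(sums_absent, dtype=float)
    y = np.asarray(sums_present, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    u = _u_statistic(x, y)
    if np.ptp(np.concatenate([x, y])) == 0:
        warnings.warn("all values tied across both groups", stacklevel=2)
        return TestResult(
            "mann-whitney U", u, 1.0, n1=x.size, n2=y.size, note="all tied"
        )
    if x.size + y.size <= EXACT_MW_MAX_N:
        p = _exact_mw_pvalue(x, y)
        note = "exact enumeration"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        note = "normal approximation, tie/continuity corrected"
    return TestResult("mann-whitney U", u, p, n1=x.size, n2=y.size, note=note)


@dataclass
class TimeSummary:
    """Mean ± SE and range of per-event minutes under one scenario."""

    mean: float
    se: float
    min: float
    max: float
    n: int
    note: str = ""


def time_in_area_summary(
    events: Sequence[Event], scenario: Scenario | str = Scenario.ALL
) -> TimeSummary:
    """Per-event time in sight under a scenario: mean, SE, min, max, n.

    Events with no blocks in the scenario are not observations of that
    scenario and are excluded.  SE = sd/sqrt(n) (sample sd); with n = 1
    the SE is reported as 0 and flagged in ``note``.
    """
    if not events:
        raise ValueError("time_in_area_summary requires at least one event")
    scenario = Scenario(scenario)
    per_event = [
        sum(b.duration for b in _scenario_blocks(e, scenario)) for e in events
    ]
    values = np.asarray([v for v in per_event if v > 0], dtype=float)
    if values.size == 0:
        return TimeSummary(0.0, 0.0, 0.0, 0.0, 0, note="no events in scenario")
    if values.size == 1:
        return TimeSummary(
            float(values[0]), 0.0, float(values[0]), float(values[0]), 1,
            note="n=1: SE undefined, reported as 0",
        )
    return TimeSummary(
        mean=float(values.mean()),
        se=float(values.std(ddof=1) / math.sqrt(values.size)),
        min=float(values.min()),
        max=float(values.max()),
        n=int(values.size),
    )
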