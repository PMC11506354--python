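# vesselbehav

Analysis pipeline for land-based surveys of vessel effects on dolphin
group behavior, built around the standard control/impact design used in
cetacean disturbance ecology.

Shore-based observers follow a dolphin group continuously once sighted,
recording per minute the group's behavioral state — feeding activities
(FEE), traveling (TRA), socializing (SOC), resting (RES) — whether a
vessel is within a ~200 m proximity radius, and the group's reaction to
it (positive approach/bowriding, neutral, or negative disruption).
`vesselbehav` turns those records into the three analyses this design
supports:

1. **Activity budgets.** Ticks are aggregated into 5-min sampling blocks
   carrying the *dominant* (modal) state; blocks separated by less than
   15 min belong to one *event*, the independence/clustering unit.
   Time per state is summed per event and compared between the
   vessel-absent and vessel-present scenarios with a two-sided
   Mann–Whitney U (exact enumeration for pooled n ≤ 12, tie-corrected
   normal approximation otherwise), with Shapiro–Wilk/Levene
   diagnostics recorded along the way.
2. **Reactions to vessels.** Vessel-present time is summed per
   (event, behavior, reaction) cell and modeled with generalized
   estimating equations: gamma family, events as clusters, exchangeable
   working correlation, robust (sandwich) errors. Three nested models —
   `M1: time ~ reaction`, `M2: + behavior`, `M3: + reaction:behavior` —
   are compared by Wald tests of the extra coefficients
   (reference levels: neutral reaction, traveling).
3. **Behavioral transitions.** First-order Markov chains are estimated
   separately for the control (no vessel) and impact (vessel present)
   scenarios as `p_ij = a_ij / Σ_j a_ij` over consecutive within-event
   blocks, with a within-event label-permutation test for per-cell
   differences and DOT diagram export.

Because field data of this kind are rarely deposited, the package ships
a first-class synthetic survey generator (`synthetic_survey`) whose
defaults emulate the target survey regime (8-h sessions, 2–132 min
sightings, ~43% vessel-present blocks, distinct control/impact
transition matrices, state-conditional reaction probabilities). Every
pipeline stage is validated against brute-force oracles and by
parameter recovery from this generator.

## Worked example

```python
from vesselbehav import (
    SimulationConfig, generate_survey, make_blocks, segment_events,
    activity_budget, count_transitions, transition_probabilities,
)

cfg = SimulationConfig()          # default: 147 sessions of 8 h
records = generate_survey(cfg, seed=1)
events = segment_events(make_blocks(records))
print(len(events), "events,", sum(len(e.blocks) for e in events), "blocks")

budget = activity_budget(events, "ALL")
print(budget.per_state.round(1))

control, impact = count_transitions(events, "preceding")
print(transition_probabilities(impact).as_frame().round(2))
```

prints

```
64 events, 574 blocks
       minutes  percent  n_blocks
state
FEE      956.0     34.9       202
TRA     1726.0     62.9       360
SOC       60.0      2.2        12
RES        0.0      0.0         0

      FEE   TRA   SOC  RES
FEE  0.62  0.38  0.00  0.0
TRA  0.19  0.78  0.03  0.0
SOC  0.25  0.75  0.00  0.0
RES   NaN   NaN   NaN  NaN
```

— a survey of 64 independent sightings whose overall budget is
dominated by traveling, and an impact chain in which traveling is
sticky (`p_TRA,TRA = 0.78` here at study scale) while resting was never
observed, so its row is reported as "no data" rather than zeros.

The same pipeline runs from the shell:

```bash
vesselbehav simulate --out records.csv --seed 1
vesselbehav segment --in records.csv --out-blocks blocks.csv --out-events events.csv
vesselbehav markov --events blocks.csv --perms 500 --out chains.json --dot chains.dot
vesselbehav run --outdir results/        # full bundle + report.md
```

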