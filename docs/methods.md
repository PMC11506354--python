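# Methods

## Data model

The atomic observation is a per-minute *tick* for one dolphin group in
one session: behavioral state (FEE, TRA, SOC, RES), a boolean "vessel
within the proximity radius" judgment (the radius, conventionally
~200 m, is applied by the observers; the package never computes
distances), and a reaction category (POS/NEU/NEG, or NONE whenever no
vessel is near — validation enforces that implication). Timestamps are
integer minutes from session start; no statistic in the pipeline needs
calendar dates, so none are modeled.

Ticks are tiled into 5-min sampling blocks from the first tick of each
continuous sighting; the final block of a sighting may be truncated and
contributes its true minutes everywhere ("time spent" is always the
block duration, never a nominal 5). Block attributes:

- **state** — the dominant (modal) state of the block's ticks. Ties are
  broken by the state occupying the latest tick: deterministic,
  independent of the label alphabet, and biased toward the state in
  effect when the block closed.
- **vessel_present** — true if *any* tick in the block has a vessel.
  This is the conservative exposure definition (presence at any time);
  whether a vessel arriving mid-block should reclassify the whole block
  is genuinely open, so the any-tick rule is a documented choice, not a
  claim.
- **reaction** — modal non-NONE tick reaction; ties go to the most
  disruptive category (NEG > NEU > POS), conservative for impact
  detection; NONE for vessel-absent blocks.

Blocks separated by a gap of **15 min or more** start a new *event*;
gaps strictly below 15 min merge. Exactly 15 min is treated as
sufficient separation (the independence interval is a minimum gap).
Events never span sessions or group streams. The event is the unit of
independence and the cluster for every inferential statistic.

## Activity budgets

Per-event minutes per state are summed for three scenarios — ABSENT,
PRESENT (by the block vessel flag) and ALL — and percentages taken over
the scenario total; percentages always sum to 100 over the observed
states, and ABSENT + PRESENT minutes equal ALL by construction (both
are asserted in the tests). States with fewer than `min_samples = 12`
blocks overall are excluded from hypothesis tests but never from
descriptive budgets; the default reproduces the common practice of
dropping a state observed only ~10 times across a year-long survey.

Scenario comparisons use a two-sided Mann–Whitney U on per-event sums.
For pooled n ≤ 12 the p-value is computed by exhaustive enumeration of
all group assignments, with the two-sided value defined as twice the
smaller one-sided tail (clipped at 1): with ties the permutation
distribution of U is not symmetric, so tail-doubling — the convention
of standard software — is used rather than deviation counting. For
larger samples the tie- and continuity-corrected normal approximation
(scipy) is used. Shapiro–Wilk and Levene checks are computed and
recorded, but never gate the analysis: the pipeline is nonparametric
regardless, which is the honest description of how such data are
actually treated. Outliers are retained.

## Reaction-time GEE models

Vessel-present block minutes are summed per (event, behavior, reaction)
cell; zero-time cells are absent rather than imputed because the gamma
support excludes zero — consequently the design is informative only
about observed cells. The model suite is

- M1: time ~ reaction
- M2: time ~ reaction + behavior
- M3: time ~ reaction + behavior + reaction:behavior

fitted as marginal gamma-family GEE with events as clusters and an
exchangeable working correlation (statsmodels backend; the module owns
design construction, NEU/TRA reference coding, nesting checks and Wald
machinery). The default link is the canonical inverse power; log is
selectable, and results always carry the link used. Standard errors
are robust sandwich estimates; per-coefficient tests are Wald
χ²(1) = (β̂/SE)²; nested pairs are compared by a Wald test of the
larger model's extra coefficients under its robust covariance, with df
equal to the number of extra coefficients and p from the χ² reference
distribution (no small-sample correction). Identical designs (df = 0)
and non-nested pairs are refused.

Validation limits: with the independence working structure and
singleton clusters the fit coincides with an ordinary gamma GLM to
1e-6; duplicating every cluster leaves coefficients exactly unchanged
under independence (the estimating equation is a sum over clusters) and
changes them only through finite-sample df corrections of the α/scale
moment estimators under exchangeable (≤1e-4 in practice).

## Control/impact Markov chains

Every ordered pair of consecutive blocks within an event is one
transition; transitions never cross events. Each transition is assigned
to a scenario by an exposure rule — `preceding` (default: the response
follows the stimulus, so the earlier block's flag decides),
`succeeding`, or `both` (impact only when both blocks are exposed) —
and every rule assigns each transition to exactly one scenario, so
CONTROL + IMPACT counts always equal the total pair count. Outputs are
always labeled with the rule used. Counts are row-normalized,
`p_ij = a_ij / Σ_j a_ij`, over the four-state ethogram; rows never left
from (e.g., resting in a survey where it never occurs) are reported as
"no data" (NaN), never as zeros, to avoid fabricating absorbing states.
Self-transitions are counted.

Chain differences are assessed with a permutation test that shuffles
scenario labels over transitions within each event (preserving each
event's label counts), recomputing both chains per permutation; the
per-cell two-sided p is the add-one estimate on |Δp_ij|. The test is
seed-deterministic and calibrated near the nominal level on
well-supported cells (verified at 500 null simulations).

Diagrams are exported as DOT digraphs with edge probabilities printed
to 2 decimals, the usual rendering precision for these figures.

## Synthetic survey generator

The generator exists so that every stage above can be checked by
parameter recovery, and its defaults *are* the survey regime the
package targets:

- **Sessions**: 147 sessions of 480 min (a year of alternate-day 8-h
  watches), scanned in 5-min cycles.
- **Sightings**: per-scan hazard 0.005 when no group is in sight, which
  yields on the order of 60–70 events covering roughly 4–5% of effort;
  durations follow a shifted geometric with mean 44 min clipped to
  [2, 132] min, matching the reported range of group sightings; a
  built-in lockout of the 15-min independence interval after each
  sighting guarantees that segmentation recovers the generated events
  exactly.
- **States**: first-order Markov at block granularity; the transition
  out of a block uses the impact matrix iff that block is
  vessel-present (consistent with the `preceding` estimation rule).
  Default control/impact matrices embed the stay-probabilities and
  contrasts characteristic of vessel disturbance in this system —
  control TRA→TRA 0.73, FEE→FEE 0.60, SOC→TRA 0.60; impact TRA→TRA
  0.79, FEE→FEE 0.59, FEE→TRA 0.41, TRA→FEE 0.18, FEE→SOC 0 — with the
  remaining cells filled to make rows stochastic and the RES row
  unreachable (initial distribution (0.37, 0.61, 0.02, 0)).
- **Vessels**: a two-state persistence process at block scale
  (arrive 0.3, leave 0.4 → stationary presence ≈ 0.43, matching the
  roughly 43% of vessel-present samples such surveys report);
  `VesselProcess.bernoulli(p)` gives the memoryless case.
- **Reactions**: drawn per vessel-present block conditionally on state,
  defaults weighted to a predominantly neutral profile (≈80% neutral,
  ≈16% negative, ≈4% positive of exposure time).
- **Tick noise**: optional minority-state ticks within blocks (capped
  below half the block) to exercise the dominant-state rule without
  changing the block's modal state.

One explicit pseudorandom stream per survey; identical seed, identical
records. What the generator does *not* emulate: observer error,
detection that varies with sea state or distance, group re-identification
across sessions, reaction durations within blocks (reaction is a
per-block category, matching how exposure time is aggregated), or
multi-group interactions. Passing recovery tests therefore demonstrates
the correctness of the estimators under the stated model, not
robustness to those field realities.

The companion `generate_gee_dataset` produces clustered gamma response
times with known marginal coefficients: the marginal mean is g⁻¹(x'β),
the marginal variance φμ², and within-cluster exchangeable correlation
α is induced by a shared event-level gamma multiplier. The
multiplicative construction supports α ∈ [0, 1) only; fitted negative
working correlations near zero are covered by the α = 0 case.

## Problem sizes and numerical choices

- Oracle-equivalence runs use 1,000 randomized small surveys compared
  exactly (integer minutes throughout makes exact comparison valid).
- Markov recovery simulates ≈100k/70k control/impact transitions (well
  above the 10,000-per-scenario floor) so that simultaneous 3·SE bands
  over ~40 cells are not dominated by multiplicity.
- GEE recovery uses 200 clusters × 100 replicates; the null
  model-comparison calibration uses 400 clusters × 500 replicates —
  at 200 clusters the sandwich Wald test is measurably anti-conservative
  (~8%), a known finite-cluster property of robust Wald tests rather
  than an implementation issue.
- Row-stochasticity is validated to 1e-12; budget percentage closure to
  1e-9; the GLM limit to 1e-6.
- Degenerate inputs: empty scenario selections yield flagged empty
  tables; all-tied Mann–Whitney inputs return p = 1 with a warning;
  single-event summaries report SE = 0 with an n = 1 flag; events with
  fewer than two blocks contribute no transitions.

## Known limitations

- The GEE suite assumes the three fixed model formulas; arbitrary
  designs are out of scope.
- The permutation chain test permutes labels within events, which is
  exact under exchangeability of exposure labels given the event but
  does not model serial dependence of vessel presence within an event;
  its calibration under the persistent-vessel generator is verified
  empirically at the null.
- Negative exchangeable correlations cannot be generated (only
  fitted).
- Stationary-distribution budgets, bout-length corrections and
  recovery-time analyses are deliberately not implemented.
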