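"""Budget tallies, rare-state exclusion, and nonparametric comparisons."""

import numpy as np
import pytest
from scipy import stats

from vesselbehav import (
    Scenario,
    activity_budget,
    compare_budgets,
    exclude_rare_states,
    normality_checks,
    time_in_area_summary,
)
from vesselbehav.obs_model import (
    BehaviorState,
    Event,
    ReactionType,
    SampleBlock,
)

from conftest import small_config
from oracles import oracle_budget


def _event(event_id, specs, session="S1", group="G1"):
    """specs: list of (state, duration, vessel) tuples."""
    blocks = []
    t = 0
    for i, (state, duration, vessel) in enumerate(specs):
        blocks.append(
            SampleBlock(
                session_id=session, group_id=group, block_index=i, start=t,
                duration=duration, state=BehaviorState(state),
                vessel_present=vessel,
                reaction=ReactionType.NEU if vessel else ReactionType.NONE,
                event_id=event_id,
            )
        )
        t += duration
    return Event(event_id, session, group, blocks)


class TestActivityBudget:
    def test_single_state_event_is_100_percent(self):
        table = activity_budget([_event("E1", [("TRA", 5, False)] * 3)])
        assert table.percent("TRA") == 100.0
        assert table.percent("FEE") == 0.0

    def test_percentages_sum_to_100(self, medium_events):
        for scen in Scenario:
            table = activity_budget(medium_events, scen)
            if not table.empty:
                assert table.per_state["percent"].sum() == pytest.approx(
                    100.0, abs=1e-9
                )

    def test_scenario_partition_conserves_minutes(self, medium_events):
        t_all = activity_budget(medium_events, "ALL").total_minutes
        t_a = activity_budget(medium_events, "ABSENT").total_minutes
        t_p = activity_budget(medium_events, "PRESENT").total_minutes
        assert t_a + t_p == pytest.approx(t_all)

    def test_matches_brute_force_tally(self, medium_events):
        for scen in ("ALL", "ABSENT", "PRESENT"):
            table = activity_budget(medium_events, scen)
            oblocks = [
                {"state": b.state.value, "duration": b.duration,
                 "vessel": b.vessel_present}
                for e in medium_events for b in e.blocks
            ]
            want = oracle_budget(oblocks, None, scen)
            for state in ("FEE", "TRA", "SOC", "RES"):
                assert table.per_state.loc[state, "minutes"] == pytest.approx(
                    want.get(state, 0.0)
                )

    def test_empty_selection_flagged(self):
        event = _event("E1", [("TRA", 5, False)])
        with pytest.warns(UserWarning, match="no blocks"):
            table = activity_budget([event], "PRESENT")
        assert table.empty and table.total_minutes == 0

    def test_budget_converges_to_chain_occupancy(self):
        """Empirical state shares approach the chain's stationary
        occupancy on a long vessel-free survey."""
        from vesselbehav import generate_survey, make_blocks, segment_events
        from vesselbehav.synthetic_survey import DurationModel, VesselProcess

        cfg = small_config(
            n_sessions=300, session_length=480, sighting_hazard=0.1,
            duration=DurationModel(2, 40.0, 132),
            vessel=VesselProcess.bernoulli(0.0),
        )
        events = segment_events(make_blocks(generate_survey(cfg, seed=77)))
        table = activity_budget(events, "ALL")
        P = np.asarray(cfg.P_control)
        # stationary distribution of the control chain on its support
        w, v = np.linalg.eig(P[:3, :3].T)
        pi = np.real(v[:, np.argmax(np.real(w))])
        pi = pi / pi.sum()
        shares = table.per_state["percent"].to_numpy()[:3] / 100
        n = table.per_state["n_blocks"].sum()
        se = np.sqrt(pi * (1 - pi) / n)
        # 3*SE plus slack for initial-distribution transients
        assert (np.abs(shares - pi) <= 3 * se + 0.02).all()


class TestExcludeRareStates:
    def test_state_below_threshold_excluded(self):
        events = [_event("E1", [("TRA", 5, False)] * 20 + [("SOC", 5, False)] * 11)]
        _, report = exclude_rare_states(events, min_samples=12)
        assert "SOC" in report["excluded"]
        assert report["excluded"]["SOC"] == 11
        assert "TRA" in report["kept"]

    def test_abundant_states_kept(self):
        events = [_event("E1", [(s, 5, False) for s in
                                ("FEE", "TRA", "SOC", "RES") for _ in range(12)])]
        _, report = exclude_rare_states(events, min_samples=12)
        assert report["excluded"] == {}

    def test_zero_threshold_excludes_nothing(self):
        events = [_event("E1", [("TRA", 5, False)])]
        blocks, report = exclude_rare_states(events, min_samples=0)
        assert report["excluded"] == {}
        assert len(blocks) == 1


class TestNormalityChecks:
    def test_identical_constant_vectors_levene_zero(self):
        shapiros, levene = normality_checks([3.0] * 5, [3.0] * 5)
        assert levene.statistic == 0.0 and levene.p_value == 1.0

    def test_gaussian_data_rarely_rejected(self):
        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(200):
            x = rng.normal(size=50)
            shapiros, _ = normality_checks(x, rng.normal(size=50))
            pvals.append(shapiros[0].p_value)
        # under H0 the Shapiro p-value is roughly uniform
        assert 0.02 < np.mean(np.array(pvals) < 0.05) < 0.10
        assert abs(np.mean(pvals) - 0.5) < 0.08

    def test_heavy_tailed_data_rejected_more_than_nominal(self):
        rng = np.random.default_rng(2)
        rejections = 0
        for _ in range(100):
            x = rng.standard_cauchy(size=50)
            shapiros, _ = normality_checks(x, rng.normal(size=50))
            rejections += shapiros[0].p_value < 0.05
        assert rejections > 50

    def test_insufficient_n_is_informative(self):
        with pytest.raises(ValueError, match="n >= 3"):
            normality_checks([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCompareBudgets:
    def test_identical_samples_p_near_one(self):
        r = compare_budgets([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.p_value > 0.9

    def test_all_tied_returns_p_one_with_warning(self):
        with pytest.warns(UserWarning, match="tied"):
            r = compare_budgets([5, 5, 5], [5, 5])
        assert r.p_value == 1.0

    def test_exact_enumeration_matches_scipy_permutation_oracle(self):
        """For every pooled size <= 12 tried (including ties), the exact
        p equals scipy's full-enumeration permutation test on U."""
        rng = np.random.default_rng(3)
        cases = []
        for n1 in (2, 3, 4, 5, 6):
            for n2 in (2, 4, 6):
                if n1 + n2 <= 12:
                    cases.append((rng.integers(0, 5, n1), rng.integers(0, 5, n2)))
                    cases.append((rng.normal(size=n1), rng.normal(size=n2)))
        for x, y in cases:
            got = compare_budgets(x, y)
            if np.ptp(np.concatenate([x, y])) == 0:
                continue
            ref = stats.permutation_test(
                (np.asarray(x, float), np.asarray(y, float)),
                lambda a, b, axis=-1: stats.mannwhitneyu(
                    a, b, alternative="two-sided", axis=axis
                ).statistic,
                permutation_type="independent",
                n_resamples=np.inf,
                alternative="two-sided",
                vectorized=True,
            )
            assert got.p_value == pytest.approx(min(ref.pvalue, 1.0), abs=1e-12)

    def test_large_sample_power_against_shift(self):
        rng = np.random.default_rng(4)
        rejected = 0
        for _ in range(100)[:50]:
            x = rng.normal(0, 1, 40)
            y = rng.normal(1.2, 1, 40)
            rejected += compare_budgets(x, y).p_value < 0.05
        assert rejected > 45

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_budgets([], [1.0])


class TestTimeInArea:
    def test_single_event(self):
        s = time_in_area_summary([_event("E1", [("TRA", 5, False)] * 6)], "ABSENT")
        assert (s.mean, s.se, s.n) == (30.0, 0.0, 1)
        assert "n=1" in s.note

    def test_two_events_arithmetic(self):
        events = [
            _event("E1", [("TRA", 5, False), ("TRA", 5, False)], group="G1"),
            _event("E2", [("FEE", 5, False)] * 4, group="G2"),
        ]
        s = time_in_area_summary(events, "ABSENT")
        assert (s.mean, s.min, s.max, s.n) == (15.0, 10.0, 20.0, 2)

    def test_matches_direct_recomputation(self, medium_events):
        s = time_in_area_summary(medium_events, "PRESENT")
        per_event = [
            sum(b.duration for b in e.blocks if b.vessel_present)
            for e in medium_events
        ]
        vals = np.array([v for v in per_event if v > 0], float)
        assert s.mean == pytest.approx(vals.mean())
        assert s.se == pytest.approx(vals.std(ddof=1) / np.sqrt(len(vals)))
        assert (s.min, s.max, s.n) == (vals.min(), vals.max(), len(vals))
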