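import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rxpersist.episodes import (
    DISCONTINUED,
    ONGOING,
    CoverageSegment,
    build_coverage,
    classify_trajectory,
    derive_episodes,
    detect_switches,
    discontinuation_followup,
    reinitiation_followup,
    resolve_days_supply,
    summarize_trajectories,
)

from conftest import random_fill_stream, scan_episodes_daily, segments_from_fills


class TestResolveDaysSupply:
    def test_quantity_times_per_unit(self):
        assert resolve_days_supply("A", 2, {"A": 30}) == 60

    def test_configured_fallback_for_unknown_code(self):
        assert resolve_days_supply("ZZZ", 1, {"A": 30}, default=30) == 30

    def test_unknown_code_without_default_raises(self):
        with pytest.raises(KeyError):
            resolve_days_supply("ZZZ", 1, {"A": 30})

    def test_nonpositive_quantity_rejected(self):
        with pytest.raises(ValueError):
            resolve_days_supply("A", -1, {"A": 30})


class TestBuildCoverage:
    def test_early_refill_stockpiles_into_single_segment(self):
        segs = build_coverage([0, 20], [30, 30])
        assert [(s.start_day, s.end_day) for s in segs] == [(0, 60)]

    def test_single_fill(self):
        segs = build_coverage([0], [90])
        assert [(s.start_day, s.end_day) for s in segs] == [(0, 90)]

    def test_gap_preserved(self):
        segs = build_coverage([0, 100], [30, 30])
        assert [(s.start_day, s.end_day) for s in segs] == [(0, 30), (100, 130)]

    def test_without_stockpiling_overlap_is_wasted(self):
        segs = build_coverage([0, 20], [30, 30], stockpiling=False)
        assert [(s.start_day, s.end_day) for s in segs] == [(0, 50)]

    def test_same_day_fills_summed(self):
        segs = build_coverage([5, 5], [10, 20])
        assert [(s.start_day, s.end_day) for s in segs] == [(5, 35)]
        assert segs[0].n_fills == 2

    @given(st.data())
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_stockpiling_conserves_dispensed_days(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        days, supplies = random_fill_stream(rng)
        segs = build_coverage(days, supplies)
        assert sum(s.length for s in segs) == sum(supplies)
        # disjoint and sorted
        for a, b in zip(segs, segs[1:]):
            assert a.end_day < b.start_day

    @given(st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_stockpiling_matches_daily_supply_counter(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        days, supplies = random_fill_stream(rng, max_fills=5)
        mine = [(s.start_day, s.end_day) for s in build_coverage(days, supplies)]
        ref = [(s.start_day, s.end_day) for s in segments_from_fills(days, supplies)]
        assert mine == ref


class TestDeriveEpisodes:
    def test_discontinuation_day_is_supply_end_plus_grace(self):
        eps = derive_episodes([CoverageSegment(0, 60)], 90, 400)
        assert len(eps) == 1
        assert eps[0].status == DISCONTINUED
        assert eps[0].discontinuation_day == 150

    def test_long_gap_splits_into_two_episodes(self):
        segs = [CoverageSegment(0, 60), CoverageSegment(200, 230)]
        eps = derive_episodes(segs, 90, 400)
        assert eps[0].discontinuation_day == 150
        assert eps[0].reinitiation_day == 200
        assert eps[1].status == DISCONTINUED and eps[1].discontinuation_day == 320
        # shorter follow-up leaves the second episode ongoing
        eps = derive_episodes(segs, 90, 300)
        assert eps[1].status == ONGOING and eps[1].discontinuation_day is None

    def test_gap_within_grace_stays_one_episode(self):
        segs = [CoverageSegment(0, 60), CoverageSegment(140, 170)]
        eps = derive_episodes(segs, 90, 400)
        assert len(eps) == 1
        assert eps[0].supply_end_day == 170

    def test_idempotent_on_own_episode_segments(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            days, supplies = random_fill_stream(rng)
            segs = build_coverage(days, supplies)
            eps = derive_episodes(segs, 90, 1500)
            # rebuild segments spanning each episode's full supply interval
            merged = [CoverageSegment(e.start_day, e.supply_end_day) for e in eps]
            eps2 = derive_episodes(merged, 90, 1500)
            assert [
                (e.start_day, e.supply_end_day, e.status, e.discontinuation_day)
                for e in eps
            ] == [
                (e.start_day, e.supply_end_day, e.status, e.discontinuation_day)
                for e in eps2
            ]

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_agrees_with_daily_scanner(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        grace = data.draw(st.sampled_from([30, 60, 90, 180, 365]))
        days, supplies = random_fill_stream(rng)
        segs = build_coverage(days, supplies)
        eps = derive_episodes(segs, grace, 1300)
        expected = scan_episodes_daily(segs, grace, 1300)
        got = [
            (e.start_day, e.supply_end_day, e.discontinuation_day, e.reinitiation_day)
            for e in eps
        ]
        assert got == expected

    @given(st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_discontinuation_count_monotone_in_grace(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        days, supplies = random_fill_stream(rng)
        segs = build_coverage(days, supplies)
        counts = [
            sum(e.status == DISCONTINUED for e in derive_episodes(segs, g, 1300))
            for g in (60, 90, 180, 365)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_every_covered_day_in_exactly_one_episode(self):
        rng = np.random.default_rng(17)
        days, supplies = random_fill_stream(rng)
        segs = build_coverage(days, supplies)
        eps = derive_episodes(segs, 90, 1300)
        for seg in segs:
            owners = [
                e for e in eps if e.start_day <= seg.start_day and seg.end_day <= e.supply_end_day
            ]
            assert len(owners) == 1


class TestFollowup:
    def test_reinitiation_time(self):
        eps = derive_episodes(
            [CoverageSegment(0, 60), CoverageSegment(200, 240)], 90, 500
        )
        records = reinitiation_followup(eps, None, None, 500)
        assert records == [(50, 1)]

    def test_no_reinitiation_censored_at_study_end(self):
        eps = derive_episodes([CoverageSegment(0, 60)], 90, 500)
        assert reinitiation_followup(eps, None, None, 500) == [(350, 0)]

    def test_death_is_competing_event(self):
        eps = derive_episodes([CoverageSegment(0, 60)], 90, 180)
        assert reinitiation_followup(eps, 180, None, 500) == [(30, 2)]

    def test_first_discontinuation_only_by_default(self):
        segs = [CoverageSegment(0, 60), CoverageSegment(300, 330), CoverageSegment(700, 720)]
        eps = derive_episodes(segs, 90, 2000)
        assert len(reinitiation_followup(eps, None, None, 2000)) == 1
        assert len(reinitiation_followup(eps, None, None, 2000, first_only=False)) == 3

    def test_discontinuation_followup_event_and_censoring(self):
        eps = derive_episodes([CoverageSegment(100, 160)], 90, 600)
        assert discontinuation_followup(eps, 100, None, None, 600) == (150, 1)
        # death before the discontinuation day is the competing event
        eps = derive_episodes([CoverageSegment(100, 160)], 90, 200)
        assert discontinuation_followup(eps, 100, 200, None, 600) == (100, 2)

    def test_supply_end_event_time_convention(self):
        eps = derive_episodes([CoverageSegment(100, 160)], 90, 600)
        t, e = discontinuation_followup(
            eps, 100, None, None, 600, event_time="supply_end"
        )
        assert (t, e) == (60, 1)


class TestSwitches:
    def test_category_switch_detected(self):
        switches = detect_switches(
            [0, 30, 60], ["L", "L", "S"], ["liraglutide", "liraglutide", "semaglutide"]
        )
        assert len(switches) == 1
        assert switches[0].from_category == "liraglutide"
        assert switches[0].to_category == "semaglutide"
        assert switches[0].day == 60

    def test_single_code_no_switch(self):
        assert detect_switches([0, 30], ["L", "L"], ["x", "x"]) == []

    def test_switch_within_other_category(self):
        switches = detect_switches([0, 30], ["EXE", "LIX"], ["other", "other"])
        assert len(switches) == 1
        assert switches[0].from_category == switches[0].to_category == "other"


class TestTrajectories:
    def test_continuous_coverage_is_single_continued_event(self):
        eps = derive_episodes([CoverageSegment(0, 1200)], 90, 1500)
        path = classify_trajectory(eps, [], 0, None, None)
        assert [k for _, k, _ in path.events] == ["continued"]
        assert path.terminal_state == "continued"

    def test_discontinue_reinitiate_continue(self):
        segs = [CoverageSegment(0, 310), CoverageSegment(600, 1200)]
        eps = derive_episodes(segs, 90, 1500)
        path = classify_trajectory(eps, [], 0, None, None)
        assert [k for _, k, _ in path.events] == [
            "discontinuation",
            "reinitiation",
            "continued",
        ]
        assert path.terminal_state == "continued"
        assert path.ever_reinitiated

    def test_switch_then_discontinuation(self):
        segs = [CoverageSegment(0, 810)]
        eps = derive_episodes(segs, 90, 1500)
        from rxpersist.episodes import SwitchEvent

        sw = [SwitchEvent(100, "L", "S", "liraglutide", "semaglutide")]
        path = classify_trajectory(eps, sw, 0, None, None)
        assert [k for _, k, _ in path.events] == ["switch", "discontinuation"]
        assert path.terminal_state == "discontinued"

    def test_death_truncates_path(self):
        eps = derive_episodes([CoverageSegment(0, 200)], 90, 500)
        path = classify_trajectory(eps, [], 0, 500, None)
        assert path.terminal_state == "died_or_emigrated"
        assert path.events[-1][1] == "death_or_emigration"

    def test_path_truncated_at_max_events(self):
        segs = [CoverageSegment(200 * i, 200 * i + 30) for i in range(5)]
        eps = derive_episodes(segs, 90, 1500)
        path = classify_trajectory(eps, [], 0, None, None, max_events=5)
        assert len(path.events) == 5
        # terminal state is still assessed at the horizon itself
        assert path.terminal_state == "discontinued"


class TestSummary:
    def test_hand_counted_percentages(self):
        from rxpersist.episodes import TrajectoryPath

        paths = [
            TrajectoryPath((), "discontinued", ever_reinitiated=True),
            TrajectoryPath((), "discontinued"),
            TrajectoryPath((), "continued"),
            TrajectoryPath((), "died_or_emigrated"),
        ]
        s = summarize_trajectories(paths)
        assert s.pct_discontinued == 50.0
        assert s.pct_reinitiated_among_discontinued == 50.0

    def test_all_continued(self):
        from rxpersist.episodes import TrajectoryPath

        s = summarize_trajectories([TrajectoryPath((), "continued")] * 3)
        assert s.pct_discontinued == 0.0
        assert s.pct_continued == 100.0

    def test_terminal_percentages_conserve_total(self, small_registry):
        from rxpersist.episodes import build_coverage, derive_episodes

        cfg, fills, persons, truth = small_registry
        paths = []
        p = persons.set_index("person_id")
        for pid, pf in fills.groupby("person_id"):
            idx = int(pf["fill_day"].min())
            if idx > cfg.study_end_day - 1095:
                continue
            import pandas as pd

            death = p.loc[pid, "death_day"]
            death = None if pd.isna(death) else int(death)
            emig = p.loc[pid, "emigration_day"]
            emig = None if pd.isna(emig) else int(emig)
            fup = min(d for d in (death, emig, cfg.study_end_day) if d is not None)
            segs = build_coverage(pf["fill_day"].to_numpy(), pf["days_supply"].to_numpy())
            eps = derive_episodes(segs, 90, fup)
            paths.append(classify_trajectory(eps, [], idx, death, emig))
        s = summarize_trajectories(paths)
        total = s.pct_discontinued + s.pct_continued + s.pct_died_or_emigrated
        assert abs(total - 100.0) <= 0.2  # rounding of three one-decimal shares
        assert s.n_discontinued + s.n_continued + s.n_died_or_emigrated == s.n
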