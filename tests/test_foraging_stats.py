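import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from foragekit.errors import ParameterError
from foragekit.foraging_stats import (
    AnalysisWindow,
    apply_track_exclusions,
    ecdf,
    events_for_tracks,
    frequency_timecourse,
    ks_compare,
    plate_mean_frequencies,
    rank_tests,
    window_event_frequency,
)
from foragekit.synthetic_data import ForagingSimParams, simulate_plate
from foragekit.track_io import StateCode

from conftest import build_track


def brute_force_ks_d(a, b):
    pooled = np.concatenate([a, b])
    fa = np.array([(a <= x).mean() for x in pooled])
    fb = np.array([(b <= x).mean() for x in pooled])
    return np.max(np.abs(fa - fb))


class TestWindows:
    def test_standard_window_definitions(self):
        loc = AnalysisWindow.local_search()
        glo = AnalysisWindow.global_search()
        assert (loc.start_s, loc.end_s) == (240.0, 480.0)
        assert (glo.start_s, glo.end_s) == (2160.0, 2400.0)

    def test_frequency_counts_onsets_per_minute(self):
        # 8 reversal onsets inside a 4-minute window at 3 fps
        chunk = "R" + "F" * 89  # one onset per 30 s
        track = build_track("F" * 720 + chunk * 8 + "F" * 720)
        events = events_for_tracks([track])[track.track_id]
        freq = window_event_frequency(track, events, AnalysisWindow.local_search())
        assert freq == 2.0

    def test_track_not_covering_window_is_ineligible(self):
        track = build_track("F" * 600, t0_offset_s=300.0)
        events = events_for_tracks([track])[track.track_id]
        assert window_event_frequency(track, events, AnalysisWindow.local_search()) is None

    def test_zero_events_gives_zero(self):
        track = build_track("F" * 1500)
        events = events_for_tracks([track])[track.track_id]
        assert window_event_frequency(track, events, AnalysisWindow.local_search()) == 0.0

    def test_counts_add_over_disjoint_windows(self):
        track, = simulate_plate(ForagingSimParams(seed=3, duration_s=600.0), 1)
        events = events_for_tracks([track])[track.track_id]
        w1 = AnalysisWindow.custom(0.0, 300.0)
        w2 = AnalysisWindow.custom(300.0, 600.0)
        whole = AnalysisWindow.custom(0.0, 600.0)
        f1 = window_event_frequency(track, events, w1)
        f2 = window_event_frequency(track, events, w2)
        fw = window_event_frequency(track, events, whole)
        assert f1 * 5 + f2 * 5 == pytest.approx(fw * 10)


class TestPlateAggregation:
    def test_plate_mean_of_track_frequencies(self):
        t1 = build_track("F" * 720 + ("R" + "F" * 29) * 24, track_id="a")  # 2/min
        t2 = build_track("F" * 720 + ("RR" + "F" * 28) * 24, track_id="b")  # also 24 onsets
        events = events_for_tracks([t1, t2])
        # hand-build different counts: use event_kind filtering on the same plate
        res = plate_mean_frequencies([t1, t2], events, AnalysisWindow.local_search())
        assert len(res) == 1
        f1 = window_event_frequency(t1, events["a"], AnalysisWindow.local_search())
        f2 = window_event_frequency(t2, events["b"], AnalysisWindow.local_search())
        assert res[0].events_per_min == pytest.approx((f1 + f2) / 2)
        assert res[0].n_tracks_used == 2

    def test_single_track_plate_passes_through(self):
        t = build_track("F" * 1500)
        events = events_for_tracks([t])
        res = plate_mean_frequencies([t], events, AnalysisWindow.local_search())
        assert res[0].events_per_min == 0.0

    def test_plate_without_eligible_tracks_warns(self):
        t = build_track("F" * 100)  # too short for the local window
        events = events_for_tracks([t])
        with pytest.warns(UserWarning, match="no eligible tracks"):
            res = plate_mean_frequencies([t], events, AnalysisWindow.local_search())
        assert res == []


class TestTimecourse:
    def test_decaying_hazard_first_bin_exceeds_last(self):
        params = ForagingSimParams(seed=6)
        tracks = simulate_plate(params, 10)
        events = events_for_tracks(tracks)
        tc = frequency_timecourse(tracks, events)
        assert tc["mean_per_min"].iloc[0] > tc["mean_per_min"].iloc[-1]

    def test_single_track_sem_zero_with_warning(self):
        t = build_track("F" * 360)
        events = events_for_tracks([t])
        with pytest.warns(UserWarning, match="SEM"):
            tc = frequency_timecourse([t], events)
        assert (tc["sem_per_min"] == 0.0).all()


class TestExclusions:
    def test_short_track_excluded(self):
        t = build_track("F" * 300 + "R" * 5 + "F" * 295)  # 200 s at 3 fps
        events = events_for_tracks([t])
        assert apply_track_exclusions([t], events) == []

    def test_track_without_complete_maneuver_excluded(self):
        t = build_track("R" * 1800)  # one reversal clipped by both boundaries
        events = events_for_tracks([t])
        assert apply_track_exclusions([t], events) == []

    def test_near_barrier_flag_excludes(self):
        states = "F" * 600 + "R" * 6 + "F" * 594
        ok = build_track(states, track_id="ok")
        flagged = build_track(states, track_id="flagged", near_barrier=True)
        events = events_for_tracks([ok, flagged])
        kept = apply_track_exclusions([ok, flagged], events)
        assert [t.track_id for t in kept] == ["ok"]


class TestEcdf:
    def test_values_and_duplicates(self):
        f = ecdf([1.0, 2.0, 3.0])
        assert f(2.0) == pytest.approx(2 / 3)
        g = ecdf([1.0, 1.0])
        assert g(1.0) == 1.0
        assert g(0.99) == 0.0

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    def test_monotone_with_correct_limits(self, values):
        f = ecdf(values)
        xs = np.linspace(min(values) - 1, max(values) + 1, 64)
        fx = f(xs)
        assert np.all(np.diff(fx) >= 0)
        assert fx[0] == 0.0 or min(values) >= xs[0]
        assert f(np.inf) == 1.0
        assert f(-np.inf) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            ecdf([])


class TestKsCompare:
    def test_identical_samples_not_discussable(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = ks_compare(a, a, n_comparisons=1)
        assert res.D == 0.0
        assert not res.discussable

    def test_disjoint_supports_give_unit_d(self):
        res = ks_compare([1, 2, 3, 4], [5, 6, 7, 8], n_comparisons=1)
        assert res.D == 1.0

    def test_d_matches_brute_force(self, rng):
        for _ in range(100):
            a = rng.normal(size=int(rng.integers(5, 40)))
            b = rng.normal(loc=rng.uniform(-1, 1), size=int(rng.integers(5, 40)))
            res = ks_compare(a, b, n_comparisons=1)
            assert abs(res.D - brute_force_ks_d(a, b)) < 1e-12

    def test_bonferroni_adjustment_and_cap(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(2.0, size=30)
        res = ks_compare(a, b, n_comparisons=5)
        assert res.p_adjusted == pytest.approx(min(1.0, res.p_raw * 5))

    def test_d_invariant_under_increasing_transform(self, rng):
        a = rng.normal(size=25)
        b = rng.normal(0.5, size=30)
        d0 = ks_compare(a, b, n_comparisons=1).D
        d1 = ks_compare(np.exp(a), np.exp(b), n_comparisons=1).D
        assert d0 == pytest.approx(d1, abs=1e-15)

    def test_effect_cutoff_flags_small_effects_not_discussable(self, rng):
        # large n makes a tiny shift significant, but D stays below 0.15
        a = rng.normal(size=20000)
        b = rng.normal(0.1, size=20000)
        res = ks_compare(a, b, n_comparisons=1)
        assert res.p_adjusted < 0.05
        assert res.D < 0.15 and not res.discussable

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            ks_compare([], [1.0], n_comparisons=1)


class TestRankTests:
    def test_two_identical_groups_near_null_midpoint(self):
        g = {"a": [1, 2, 3, 4, 5, 6], "b": [1, 2, 3, 4, 5, 6]}
        rep = rank_tests(g)
        assert rep["test"] == "mann-whitney"
        assert rep["p"] > 0.9

    def test_shifted_groups_detected(self, rng):
        hits = 0
        for i in range(40):
            local = np.random.Generator(np.random.PCG64(i))
            a = local.normal(0.0, 1.0, size=20)
            b = local.normal(2.0, 1.0, size=20)
            if rank_tests({"a": a, "b": b})["p"] < 0.05:
                hits += 1
        assert hits >= 38

    def test_three_groups_use_kruskal_dunn(self, rng):
        g = {
            "ctrl": rng.normal(0, 1, 12),
            "mutA": rng.normal(2, 1, 12),
            "mutB": rng.normal(0, 1, 12),
        }
        rep = rank_tests(g, control="ctrl")
        assert rep["test"] == "kruskal-wallis+dunn"
        pair = {r["group"]: r for r in rep["pairwise"]}
        assert set(pair) == {"mutA", "mutB"}
        assert pair["mutA"]["p_adjusted"] < pair["mutB"]["p_adjusted"]

    def test_relabeling_groups_permutes_pairwise_set(self, rng):
        vals = {k: rng.normal(i, 1, 10) for i, k in enumerate("abc")}
        rep1 = rank_tests(vals, control="a")
        swapped = {"c": vals["c"], "b": vals["b"], "a": vals["a"]}
        rep2 = rank_tests(swapped, control="a")
        p1 = sorted(r["p_raw"] for r in rep1["pairwise"])
        p2 = sorted(r["p_raw"] for r in rep2["pairwise"])
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ParameterError):
            rank_tests({"a": [1.0], "b": [1.0, 2.0]})

    def test_dunn_z_matches_textbook_formula_no_ties(self):
        groups = {
            "ctrl": np.array([1.0, 4.0, 7.0, 10.0]),
            "hi": np.array([2.0, 5.0, 8.0, 11.0]),
            "lo": np.array([3.0, 6.0, 9.0, 12.0]),
        }
        rep = rank_tests(groups, control="ctrl")
        pooled = np.concatenate(list(groups.values()))
        ranks = sps.rankdata(pooled)
        mr = {k: ranks[i * 4:(i + 1) * 4].mean() for i, k in enumerate(groups)}
        n = pooled.size
        se = math.sqrt(n * (n + 1) / 12 * (1 / 4 + 1 / 4))
        for row in rep["pairwise"]:
            z_expected = (mr[row["group"]] - mr["ctrl"]) / se
            assert row["z"] == pytest.approx(z_expected, rel=1e-12)
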