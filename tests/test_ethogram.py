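import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from foragekit import ethogram as eth
from foragekit.errors import ParameterError
from foragekit.ethogram import (
    Coupling,
    LengthClass,
    classify_reversal_lengths,
    couple_reversal_turns,
    forward_run_durations,
    make_ethogram,
    maneuver_turn_angle,
    segment_events,
)
from foragekit.synthetic_data import ForagingSimParams, simulate_foraging_track
from foragekit.track_io import StateCode

from conftest import STATE_LETTERS, build_track


def brute_force_rle(states):
    runs = []
    for s in states:
        if runs and runs[-1][0] == s:
            runs[-1][1] += 1
        else:
            runs.append([s, 1])
    return runs


class TestSegmentation:
    def test_simple_run_length_encoding(self):
        track = build_track("FFRRRF", frame_rate_hz=3.0)
        events = segment_events(track)
        assert [e.kind for e in events] == ["FORWARD", "REVERSAL", "FORWARD"]
        assert [e.duration_s for e in events] == pytest.approx([2 / 3, 1.0, 1 / 3])

    def test_all_forward_single_event(self):
        track = build_track("F" * 50)
        events = segment_events(track)
        assert len(events) == 1
        assert events[0].duration_s == pytest.approx(track.duration_s)

    def test_matches_brute_force_on_random_arrays(self, rng):
        letters = list(STATE_LETTERS)
        for _ in range(200):
            n = int(rng.integers(1, 300))
            states = "".join(rng.choice(letters, size=n))
            track = build_track(states)
            events = segment_events(track)
            oracle = brute_force_rle([STATE_LETTERS[c] for c in states])
            assert [(e.kind, e.n_frames) for e in events] == [
                (k, n) for k, n in oracle
            ]
            assert sum(e.duration_s for e in events) == pytest.approx(track.duration_s)

    def test_short_runs_absorbed_into_preceding_event(self):
        track = build_track("FFFFRFFFF")
        events = segment_events(track, min_event_frames=2)
        assert [e.kind for e in events] == ["FORWARD"]
        assert events[0].n_frames == 9

    def test_empty_track_rejected(self):
        with pytest.raises(Exception):
            segment_events(build_track(""))

    def test_recovers_simulator_ground_truth_exactly(self):
        track, gt = simulate_foraging_track(ForagingSimParams(seed=13, duration_s=900.0))
        events = segment_events(track)
        assert [(e.kind, round(e.start_s, 6)) for e in events] == [
            (t.kind, round(t.start_s, 6)) for t in gt.events
        ]


class TestEventParameters:
    def test_straight_path_length(self):
        x = 0.1 * np.arange(10)
        track = build_track("R" * 10, x=x, y=np.zeros(10), worm_length_mm=1.0)
        ev = segment_events(track)[0]
        assert ev.path_length_bl == pytest.approx(0.9)

    def test_single_frame_event_has_zero_path(self):
        track = build_track("FR", x=[0.0, 1.0])
        events = segment_events(track)
        assert events[1].path_length_bl == 0.0

    def test_path_length_at_least_net_displacement(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 40))
            x = rng.normal(size=n).cumsum()
            y = rng.normal(size=n).cumsum()
            track = build_track("R" * n, x=x, y=y)
            ev = segment_events(track)[0]
            net = math.hypot(x[-1] - x[0], y[-1] - y[0])
            assert ev.path_length_bl >= net / track.worm_length_mm - 1e-12

    def test_path_length_invariant_to_rigid_motion(self, rng):
        n = 30
        x = rng.normal(size=n).cumsum()
        y = rng.normal(size=n).cumsum()
        theta, dx, dy = 0.7, 5.0, -3.0
        xr = x * math.cos(theta) - y * math.sin(theta) + dx
        yr = x * math.sin(theta) + y * math.cos(theta) + dy
        ev0 = segment_events(build_track("R" * n, x=x, y=y))[0]
        ev1 = segment_events(build_track("R" * n, x=xr, y=yr))[0]
        assert ev1.path_length_bl == pytest.approx(ev0.path_length_bl, rel=1e-9)

    def test_event_speed_is_mean_median_average(self):
        track = build_track("RRR", speeds=[0.0, 0.0, 3.0])
        ev = segment_events(track)[0]
        assert ev.speed_mm_s == pytest.approx((1.0 + 0.0) / 2)

    @given(st.lists(st.floats(0.0, 10.0), min_size=1, max_size=30))
    def test_event_speed_within_frame_speed_range(self, speeds):
        track = build_track("R" * len(speeds), speeds=speeds)
        ev = segment_events(track)[0]
        assert min(speeds) - 1e-12 <= ev.speed_mm_s <= max(speeds) + 1e-12


class TestCoupling:
    def _events(self, states):
        return segment_events(build_track(states))

    def test_reversal_then_omega_is_coupled(self):
        events = couple_reversal_turns(self._events("FFRRROOFF"))
        rev = next(e for e in events if e.kind == "REVERSAL")
        assert rev.coupling is Coupling.REVERSAL_OMEGA

    def test_reversal_then_forward_is_pure(self):
        events = couple_reversal_turns(self._events("FFRRRFF"))
        rev = next(e for e in events if e.kind == "REVERSAL")
        assert rev.coupling is Coupling.PURE_REVERSAL

    def test_reversal_then_pause_not_classified(self):
        events = couple_reversal_turns(self._events("FFRRRPPF"))
        rev = next(e for e in events if e.kind == "REVERSAL")
        assert rev.coupling is Coupling.NOT_APPLICABLE

    def test_pause_within_gap_allows_omega_coupling(self):
        events = couple_reversal_turns(self._events("FFRRRPOOF"), max_gap_s=1.0)
        rev = next(e for e in events if e.kind == "REVERSAL")
        assert rev.coupling is Coupling.REVERSAL_OMEGA

    def test_uncoupled_omega_flagged(self):
        events = couple_reversal_turns(self._events("FFOOFF"))
        om = next(e for e in events if e.kind == "OMEGA_TURN")
        assert om.uncoupled_omega

    def test_classified_fractions_sum_to_one(self):
        track, _ = simulate_foraging_track(ForagingSimParams(seed=2, duration_s=1200.0))
        events = couple_reversal_turns(segment_events(track))
        revs = [e for e in events if e.kind == "REVERSAL"]
        classified = [e for e in revs if e.coupling is not Coupling.NOT_APPLICABLE]
        n_omega = sum(1 for e in classified if e.coupling is Coupling.REVERSAL_OMEGA)
        n_pure = sum(1 for e in classified if e.coupling is Coupling.PURE_REVERSAL)
        assert n_omega + n_pure == len(classified) > 0


class TestLengthClass:
    def test_threshold_classification(self):
        track = build_track("R" * 4 + "F" + "R" * 13,
                            speeds=[0.3] * 18)  # 0.1 mm/frame steps
        events = classify_reversal_lengths(segment_events(track))
        revs = [e for e in events if e.kind == "REVERSAL"]
        assert revs[0].path_length_bl == pytest.approx(0.3)
        assert revs[0].length_class is LengthClass.SHORT
        assert revs[1].path_length_bl == pytest.approx(1.2)
        assert revs[1].length_class is LengthClass.LONG

    def test_boundary_tie_goes_long(self):
        track = build_track("R" * 5, speeds=[0.375] * 5)  # 4 steps x 0.125 mm
        ev = classify_reversal_lengths(segment_events(track))[0]
        assert ev.path_length_bl == 0.5  # exact in binary floating point
        assert ev.length_class is LengthClass.LONG

    def test_zero_threshold_makes_all_long(self):
        track = build_track("RRRFF")
        events = classify_reversal_lengths(segment_events(track), threshold_bl=0.0)
        assert events[0].length_class is LengthClass.LONG


class TestForwardRuns:
    def test_two_second_inclusion_rule(self):
        # runs of 1.5 s, 2.0 s, 7.0 s at 2 fps
        states = "F" * 3 + "R" + "F" * 4 + "R" + "F" * 14
        events = segment_events(build_track(states, frame_rate_hz=2.0))
        durs = forward_run_durations(events)
        assert durs == pytest.approx([2.0, 7.0])

    def test_zero_minimum_keeps_all_runs(self):
        states = "FRFFRFFF"
        events = segment_events(build_track(states))
        durs = forward_run_durations(events, min_duration_s=0.0)
        assert len(durs) == 3


class TestTurnAngle:
    def _maneuver_track(self, delta_deg, rate=5.0):
        """Straight east, reverse west, omega, leave at delta from east."""
        n_pre, n_rev, n_om, n_post = 10, 5, 3, 10
        step = 0.05
        xs, ys = [0.0], [0.0]
        heading = 0.0
        for _ in range(n_pre - 1):
            xs.append(xs[-1] + step)
            ys.append(ys[-1])
        for _ in range(n_rev):
            xs.append(xs[-1] - step)
            ys.append(ys[-1])
        for _ in range(n_om):
            xs.append(xs[-1])
            ys.append(ys[-1])
        out = math.radians(delta_deg)
        for _ in range(n_post):
            xs.append(xs[-1] + step * math.cos(out))
            ys.append(ys[-1] + step * math.sin(out))
        states = "F" * n_pre + "R" * n_rev + "O" * n_om + "F" * n_post
        return build_track(states, frame_rate_hz=rate, x=xs, y=ys)

    @pytest.mark.parametrize("delta", [0.0, 150.0, 180.0, -150.0])
    def test_planted_reorientation_recovered(self, delta):
        track = self._maneuver_track(delta)
        events = segment_events(track)
        rev = next(e for e in events if e.kind == "REVERSAL")
        om = next(e for e in events if e.kind == "OMEGA_TURN")
        ang = maneuver_turn_angle(track, rev, om, heading_window_s=1.0)
        assert ang.abs_change_deg == pytest.approx(abs(delta), abs=1e-6)

    def test_insufficient_window_returns_none(self):
        track = build_track("FRRF")
        events = segment_events(track)
        rev = events[1]
        ang = maneuver_turn_angle(track, rev, rev, heading_window_s=5.0)
        assert ang is None


class TestEthogram:
    def _tracks(self, n=8):
        return [
            simulate_foraging_track(
                ForagingSimParams(seed=s, duration_s=420.0), track_id=f"t{s}"
            )[0]
            for s in range(n)
        ]

    def test_all_forward_track_maps_to_forward_row(self):
        tracks = [build_track("F" * 90, track_id="tf")]
        m = make_ethogram(tracks, (0.0, 30.0), n_tracks=1)
        assert set(m.loc["tf"]) == {"forward"}

    def test_uncoupled_omega_maps_to_other(self):
        tracks = [build_track("F" * 30 + "O" * 6 + "F" * 54, track_id="to")]
        m = make_ethogram(tracks, (0.0, 30.0), n_tracks=1)
        assert "coupled_omega" not in set(m.loc["to"])
        assert "other" in set(m.loc["to"])

    def test_coupled_omega_category_present(self):
        tracks = [build_track("F" * 30 + "R" * 6 + "O" * 6 + "F" * 48, track_id="tc")]
        m = make_ethogram(tracks, (0.0, 30.0), n_tracks=1)
        assert "coupled_omega" in set(m.loc["tc"])

    def test_fixed_seed_sampling_deterministic(self):
        tracks = self._tracks()
        m1 = make_ethogram(tracks, (60.0, 120.0), n_tracks=4, seed=9)
        m2 = make_ethogram(tracks, (60.0, 120.0), n_tracks=4, seed=9)
        assert (m1 == m2).all().all()
        assert len(m1) == 4

    def test_too_few_tracks_warns_and_uses_all(self):
        tracks = self._tracks(3)
        with pytest.warns(UserWarning, match="using all"):
            m = make_ethogram(tracks, (60.0, 120.0), n_tracks=50)
        assert len(m) == 3

    def test_render_writes_png(self, tmp_path):
        tracks = self._tracks(3)
        m = make_ethogram(tracks, (60.0, 120.0), n_tracks=3)
        out = tmp_path / "etho.png"
        eth.render_ethogram(m, out)
        assert out.stat().st_size > 0
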