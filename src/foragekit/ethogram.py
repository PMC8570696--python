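"""Event segmentation and per-event behavioral parameters.

A track's per-frame state codes are segmented into maximal runs of
identical state ("events"); events tile the track exactly.  Per event the
module computes duration, centroid path length in body lengths, and speed
(the average of the mean and median frame speed).  Reversals are classified
short/long at 0.5 body lengths and coupled to an immediately following
omega turn; reversal-turn maneuvers get an absolute turn angle from the
headings before and after.
"""
from __future__ import annotations

import dataclasses
import enum
import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import config
from .errors import ParameterError
from .track_io import StateCode, TrackRecord


class Coupling(str, enum.Enum):
    REVERSAL_OMEGA = "REVERSAL_OMEGA"
    PURE_REVERSAL = "PURE_REVERSAL"
    NOT_APPLICABLE = "NOT_APPLICABLE"


class LengthClass(str, enum.Enum):
    SHORT = "SHORT"
    LONG = "LONG"
    NOT_APPLICABLE = "NOT_APPLICABLE"


@dataclasses.dataclass
class BehaviorEvent:
    """One contiguous behavioral episode with derived parameters."""

    track_id: str
    kind: str
    start_s: float
    end_s: float
    start_frame: int
    n_frames: int
    duration_s: float
    path_length_bl: float = 0.0
    speed_mm_s: float = 0.0
    coupling: Coupling = Coupling.NOT_APPLICABLE
    length_class: LengthClass = LengthClass.NOT_APPLICABLE
    uncoupled_omega: bool = False


@dataclasses.dataclass
class ManeuverAngle:
    """Absolute heading change across one reversal-turn maneuver."""

    start_s: float
    end_s: float
    heading_before_deg: float
    heading_after_deg: float
    abs_change_deg: float


def _run_length_encode(states: np.ndarray) -> list[tuple[int, int]]:
    """(start index, run length) of maximal runs of identical values."""
    n = len(states)
    if n == 0:
        return []
    change = np.nonzero(states[1:] != states[:-1])[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def reversal_path_length(track: TrackRecord, start_frame: int, n_frames: int) -> float:
    """Summed centroid displacement over the event's frames, in body lengths."""
    sl = slice(start_frame, start_frame + n_frames)
    x = track.frames["x_mm"].to_numpy(float)[sl]
    y = track.frames["y_mm"].to_numpy(float)[sl]
    if len(x) < 2:
        return 0.0
    return float(np.hypot(np.diff(x), np.diff(y)).sum()) / track.worm_length_mm


def event_speed(track: TrackRecord, start_frame: int, n_frames: int) -> float:
    """Average of the mean and median frame speed over the event."""
    sp = track.frames["speed_mm_s"].to_numpy(float)[start_frame : start_frame + n_frames]
    return float((np.mean(sp) + np.median(sp)) / 2.0)


def segment_events(track: TrackRecord, min_event_frames: int = 1) -> list[BehaviorEvent]:
    """Segment the per-frame state sequence into tiling events.

    Runs shorter than ``min_event_frames`` are absorbed into the preceding
    event (the default of 1 performs no merging, taking the tracker's state
    calls at face value).  Event intervals are half-open in frames, so the
    summed event durations equal the track duration exactly.
    """
    if track.n_frames == 0:
        raise ParameterError("cannot segment an empty track")
    if min_event_frames < 1:
        raise ParameterError("min_event_frames must be >= 1")
    states = track.states()
    runs = _run_length_encode(states)
    if min_event_frames > 1:
        merged: list[tuple[int, int, object]] = []
        for start, n in runs:
            kind = states[start]
            if merged and (n < min_event_frames or merged[-1][2] == kind):
                s0, n0, k0 = merged[-1]
                merged[-1] = (s0, n0 + n, k0)
            else:
                merged.append((start, n, kind))
        runs = [(s, n) for s, n, _ in merged]

    dt = 1.0 / track.frame_rate_hz
    t0 = track.start_s
    events = []
    for start, n in runs:
        kind = str(states[start])
        ev = BehaviorEvent(
            track_id=track.track_id,
            kind=kind,
            start_s=t0 + start * dt,
            end_s=t0 + (start + n) * dt,
            start_frame=start,
            n_frames=n,
            duration_s=n * dt,
            speed_mm_s=event_speed(track, start, n),
        )
        if kind in (StateCode.REVERSAL.value, StateCode.FORWARD.value):
            ev.path_length_bl = reversal_path_length(track, start, n)
        events.append(ev)
    return events


def couple_reversal_turns(
    events: Sequence[BehaviorEvent], max_gap_s: float = 0.0
) -> list[BehaviorEvent]:
    """Set each reversal's coupling class from the event that follows it.

    A reversal is REVERSAL_OMEGA if an omega turn begins within
    ``max_gap_s`` of its end (default 0: immediately adjacent), and
    PURE_REVERSAL if the next event is a forward run.  Reversals followed
    by a pause, shallow turn, or other state remain NOT_APPLICABLE and are
    excluded from the two-way coupled fraction.  Omega turns not
    immediately preceded by a reversal are flagged uncoupled.
    """
    evs = list(events)
    for a, b in zip(evs, evs[1:]):
        if b.start_s < a.start_s - 1e-9:
            raise ParameterError("events must be time-ordered")
    for i, ev in enumerate(evs):
        if ev.kind == StateCode.REVERSAL.value:
            # first omega starting within the gap wins; otherwise an
            # immediately following forward run makes it a pure reversal
            omega = None
            for nxt in evs[i + 1 :]:
                if nxt.start_s > ev.end_s + max_gap_s + 1e-9:
                    break
                if nxt.kind == StateCode.OMEGA_TURN.value:
                    omega = nxt
                    break
                if nxt.kind in (StateCode.FORWARD.value, StateCode.REVERSAL.value):
                    break
            if omega is not None:
                ev.coupling = Coupling.REVERSAL_OMEGA
                omega.coupling = Coupling.REVERSAL_OMEGA
            elif i + 1 < len(evs) and evs[i + 1].kind == StateCode.FORWARD.value:
                ev.coupling = Coupling.PURE_REVERSAL
            else:
                ev.coupling = Coupling.NOT_APPLICABLE
        elif ev.kind == StateCode.OMEGA_TURN.value:
            prev = evs[i - 1] if i > 0 else None
            if prev is None or prev.kind != StateCode.REVERSAL.value:
                ev.uncoupled_omega = True
    return evs


def classify_reversal_lengths(
    events: Sequence[BehaviorEvent],
    threshold_bl: float = config.SHORT_REVERSAL_MAX_BL,
) -> list[BehaviorEvent]:
    """SHORT iff path length < threshold (ties at the boundary go LONG)."""
    evs = list(events)
    for ev in evs:
        if ev.kind == StateCode.REVERSAL.value:
            ev.length_class = (
                LengthClass.SHORT if ev.path_length_bl < threshold_bl else LengthClass.LONG
            )
    return evs


def forward_run_durations(
    events: Sequence[BehaviorEvent],
    min_duration_s: float = config.MIN_FORWARD_RUN_S,
) -> list[float]:
    """Durations of forward runs lasting at least ``min_duration_s``."""
    return [
        ev.duration_s
        for ev in events
        if ev.kind == StateCode.FORWARD.value and ev.duration_s >= min_duration_s
    ]


def _window_heading_deg(
    track: TrackRecord, start_s: float, end_s: float
) -> float | None:
    """Direction (deg) of the net displacement over [start_s, end_s)."""
    dt = 1.0 / track.frame_rate_hz
    i0 = int(round((start_s - track.start_s) * track.frame_rate_hz))
    i1 = int(round((end_s - track.start_s) * track.frame_rate_hz))
    if i0 < 0 or i1 > track.n_frames or i1 - i0 < 2:
        return None
    x = track.frames["x_mm"].to_numpy(float)
    y = track.frames["y_mm"].to_numpy(float)
    dx = x[i1 - 1] - x[i0]
    dy = y[i1 - 1] - y[i0]
    if dx == 0 and dy == 0:
        return None
    return math.degrees(math.atan2(dy, dx))


def maneuver_turn_angle(
    track: TrackRecord,
    reversal_event: BehaviorEvent,
    turn_event: BehaviorEvent,
    heading_window_s: float = 1.0,
) -> ManeuverAngle | None:
    """Absolute change in direction across a reversal-turn maneuver.

    Headings are estimated from the mean displacement over
    ``heading_window_s`` before reversal onset and after turn end; the
    change is wrapped to [0, 180] degrees.  Returns None when either
    heading window is not fully covered by the track.
    """
    before = _window_heading_deg(
        track, reversal_event.start_s - heading_window_s, reversal_event.start_s
    )
    after = _window_heading_deg(track, turn_event.end_s, turn_event.end_s + heading_window_s)
    if before is None or after is None:
        return None
    diff = (after - before + 180.0) % 360.0 - 180.0
    return ManeuverAngle(
        start_s=reversal_event.start_s,
        end_s=turn_event.end_s,
        heading_before_deg=before,
        heading_after_deg=after,
        abs_change_deg=abs(diff),
    )


ETHOGRAM_CATEGORIES = ["forward", "reversal", "coupled_omega", "other"]


def make_ethogram(
    tracks: Sequence[TrackRecord],
    interval: tuple[float, float],
    n_tracks: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-frame categorical matrix for a random sample of tracks.

    Categories: forward, reversal, coupled_omega, and other (pauses,
    shallow turns, and omega turns not preceded by a reversal).  Rows are
    sampled tracks, columns are frame times within ``interval``.
    """
    start_s, end_s = interval
    if end_s <= start_s:
        raise ParameterError("interval end must exceed start")
    eligible = [t for t in tracks if t.covers(start_s, end_s)]
    if not eligible:
        raise ParameterError("no tracks cover the requested interval")
    rng = np.random.Generator(np.random.PCG64(seed))
    if len(eligible) < n_tracks:
        warnings.warn(
            f"only {len(eligible)} tracks cover the interval; using all of them"
        )
        chosen = eligible
    else:
        idx = rng.choice(len(eligible), size=n_tracks, replace=False)
        chosen = [eligible[int(i)] for i in np.sort(idx)]

    rows = {}
    times = None
    for track in chosen:
        events = couple_reversal_turns(segment_events(track))
        dt = 1.0 / track.frame_rate_hz
        i0 = int(round((start_s - track.start_s) * track.frame_rate_hz))
        i1 = int(round((end_s - track.start_s) * track.frame_rate_hz))
        cats = np.full(i1 - i0, "other", dtype=object)
        for ev in events:
            a = max(ev.start_frame, i0)
            b = min(ev.start_frame + ev.n_frames, i1)
            if b <= a:
                continue
            if ev.kind == StateCode.FORWARD.value:
                cat = "forward"
            elif ev.kind == StateCode.REVERSAL.value:
                cat = "reversal"
            elif ev.kind == StateCode.OMEGA_TURN.value and not ev.uncoupled_omega:
                cat = "coupled_omega"
            else:
                cat = "other"
            cats[a - i0 : b - i0] = cat
        rows[track.track_id] = cats
        if times is None:
            times = track.start_s + np.arange(i0, i1) * dt
    return pd.DataFrame(rows, index=np.round(times, 6)).T


def render_ethogram(matrix: pd.DataFrame, path) -> None:
    """Render an ethogram matrix to a PNG (rows: tracks, columns: time)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    colors = {"forward": "white", "reversal": "black", "coupled_omega": "gold", "other": "0.6"}
    cat_to_int = {c: i for i, c in enumerate(ETHOGRAM_CATEGORIES)}
    codes = matrix.map(cat_to_int.__getitem__).to_numpy(int)
    cmap = ListedColormap([colors[c] for c in ETHOGRAM_CATEGORIES])
    fig, ax = plt.subplots(figsize=(8, max(2, 0.12 * len(matrix))))
    ax.imshow(codes, aspect="auto", cmap=cmap, vmin=0, vmax=len(ETHOGRAM_CATEGORIES) - 1,
              interpolation="nearest")
    ax.set_xlabel("frame")
    ax.set_ylabel("track")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def events_to_frame(events: Iterable[BehaviorEvent]) -> pd.DataFrame:
    """Flatten events to a tidy DataFrame (one row per event)."""
    rows = [
        {
            "track_id": ev.track_id,
            "kind": ev.kind,
            "start_s": ev.start_s,
            "end_s": ev.end_s,
            "duration_s": ev.duration_s,
            "path_length_bl": ev.path_length_bl,
            "speed_mm_s": ev.speed_mm_s,
            "coupling": ev.coupling.value,
            "length_class": ev.length_class.value,
            "uncoupled_omega": ev.uncoupled_omega,
        }
        for ev in events
    ]
    return pd.DataFrame(rows)
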