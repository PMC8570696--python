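"""Pulse-aligned extraction and evoked-response statistics.

Tracks are aligned around each light pulse and cut into 120 s segments
with the pulse occupying [50, 70) s of segment time; only segments fully
covered by the track are kept.  The evoked response is the change in
reversal frequency: mean frequency over an 18 s window during the pulse
([50, 68) s of segment time) minus an 18 s window immediately before onset
([32, 50) s), counting reversals by onset time.  Reversal parameters are
scored only for the first reversal of duration >= 0.5 s that begins during
the light.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import config
from .errors import ParameterError, ScheduleError
from .ethogram import BehaviorEvent
from .track_io import StateCode, TrackRecord


def validate_pulse_schedule(schedule: Sequence[tuple[float, float]]) -> None:
    sched = sorted(schedule)
    for onset, dur in sched:
        if dur <= 0:
            raise ScheduleError(f"pulse at {onset} s has non-positive duration")
    for (o1, d1), (o2, _) in zip(sched, sched[1:]):
        if o2 < o1 + d1:
            raise ScheduleError(f"pulses at {o1} s and {o2} s overlap")


@dataclasses.dataclass
class PulseWindow:
    """One pulse-aligned 120 s segment of a track.

    ``segment_start_s`` is in track time; the pulse occupies
    [pulse_offset_s, pulse_offset_s + pulse duration) of segment time.
    """

    track_id: str
    pulse_index: int
    segment_start_s: float
    pulse_onset_s: float
    pulse_duration_s: float
    freq_before_per_min: float | None = None
    freq_during_per_min: float | None = None
    first_evoked_reversal: BehaviorEvent | None = None

    @property
    def delta_per_min(self) -> float | None:
        if self.freq_before_per_min is None or self.freq_during_per_min is None:
            return None
        return self.freq_during_per_min - self.freq_before_per_min


def extract_pulse_windows(
    track: TrackRecord,
    pulse_schedule: Sequence[tuple[float, float]] | None = None,
    segment_s: float = config.PULSE_SEGMENT_S,
    pulse_offset_s: float = config.PULSE_ONSET_IN_SEGMENT_S,
) -> list[PulseWindow]:
    """One window per pulse whose whole segment the track covers."""
    schedule = pulse_schedule if pulse_schedule is not None else track.pulse_schedule
    if not schedule:
        raise ScheduleError("no pulse schedule given or stored in the track")
    validate_pulse_schedule(schedule)
    windows = []
    for i, (onset, dur) in enumerate(sorted(schedule)):
        seg_start = onset - pulse_offset_s
        if track.covers(seg_start, seg_start + segment_s):
            windows.append(
                PulseWindow(
                    track_id=track.track_id,
                    pulse_index=i,
                    segment_start_s=seg_start,
                    pulse_onset_s=onset,
                    pulse_duration_s=dur,
                )
            )
    return windows


def _onsets_in(events: Sequence[BehaviorEvent], start_s: float, end_s: float) -> int:
    return sum(
        1
        for ev in events
        if ev.kind == StateCode.REVERSAL.value and start_s <= ev.start_s < end_s
    )


def delta_reversal_frequency(
    window: PulseWindow,
    events: Sequence[BehaviorEvent],
    before_offset_s: float = config.OPTO_BEFORE_OFFSET_S,
    during_offset_s: float = config.OPTO_DURING_OFFSET_S,
    window_s: float = config.OPTO_DELTA_WINDOW_S,
) -> float:
    """During-minus-before reversal frequency (events/min) for one window.

    Both 18 s windows are placed adjacent to light onset by default:
    before = [32, 50) s and during = [50, 68) s of segment time.  Reversals
    straddling onset count by onset time only.  Fills the window's
    frequency fields and returns the delta.
    """
    seg = window.segment_start_s
    minutes = window_s / 60.0
    before = _onsets_in(events, seg + before_offset_s, seg + before_offset_s + window_s)
    during = _onsets_in(events, seg + during_offset_s, seg + during_offset_s + window_s)
    window.freq_before_per_min = before / minutes
    window.freq_during_per_min = during / minutes
    return window.delta_per_min


def first_evoked_reversal(
    window: PulseWindow,
    events: Sequence[BehaviorEvent],
    min_duration_s: float = config.MIN_EVOKED_REVERSAL_S,
) -> BehaviorEvent | None:
    """First reversal of duration >= 0.5 s starting during the light pulse."""
    light_start = window.pulse_onset_s
    light_end = window.pulse_onset_s + window.pulse_duration_s
    for ev in sorted(events, key=lambda e: e.start_s):
        if (
            ev.kind == StateCode.REVERSAL.value
            and light_start <= ev.start_s < light_end
            and ev.duration_s >= min_duration_s
        ):
            window.first_evoked_reversal = ev
            return ev
    return None


def evoked_response_summary(
    windows_by_condition: Mapping[str, Sequence[PulseWindow]],
) -> dict:
    """Per-condition mean +/- SEM delta and evoked-reversal parameter samples.

    Windows must already have their frequencies and first evoked reversals
    filled in (via :func:`delta_reversal_frequency` and
    :func:`first_evoked_reversal`).  Evoked length/speed/duration samples
    are returned for downstream ECDF / KS comparisons.
    """
    if not windows_by_condition:
        raise ParameterError("at least one condition required")
    out = {}
    for cond, windows in windows_by_condition.items():
        deltas = np.array(
            [w.delta_per_min for w in windows if w.delta_per_min is not None], dtype=float
        )
        evoked = [w.first_evoked_reversal for w in windows if w.first_evoked_reversal]
        sem = (
            float(np.std(deltas, ddof=1) / math.sqrt(deltas.size)) if deltas.size > 1 else 0.0
        )
        out[cond] = {
            "n_windows": len(windows),
            "n_deltas": int(deltas.size),
            "mean_delta_per_min": float(np.mean(deltas)) if deltas.size else float("nan"),
            "sem_delta_per_min": sem,
            "evoked_length_bl": [e.path_length_bl for e in evoked],
            "evoked_duration_s": [e.duration_s for e in evoked],
            "evoked_speed_mm_s": [e.speed_mm_s for e in evoked],
        }
    return out


def windows_to_frame(windows: Sequence[PulseWindow]) -> pd.DataFrame:
    rows = [
        {
            "track_id": w.track_id,
            "pulse_index": w.pulse_index,
            "segment_start_s": w.segment_start_s,
            "pulse_onset_s": w.pulse_onset_s,
            "pulse_duration_s": w.pulse_duration_s,
            "freq_before_per_min": w.freq_before_per_min,
            "freq_during_per_min": w.freq_during_per_min,
            "delta_per_min": w.delta_per_min,
            "evoked_reversal_start_s": (
                w.first_evoked_reversal.start_s if w.first_evoked_reversal else None
            ),
        }
        for w in windows
    ]
    return pd.DataFrame(rows)
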