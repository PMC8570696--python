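"""Containers and round-trip-stable storage for tracks and calcium traces.

A :class:`TrackRecord` is the unit of behavioral analysis: one animal's
uninterrupted centroid track, with the per-frame behavioral state code the
upstream tracker assigned.  Tracks are stored as one tidy CSV (one row per
frame) plus a JSON sidecar holding per-track metadata; calcium traces use
the same pattern.  Floats are serialized at 12 significant digits, so round
trips preserve them to better than 1e-9 relative.  Readers validate the
documented invariants and report violations with row numbers; they never
impute missing frames (tracks with gaps must be split by the producer).
"""
from __future__ import annotations

import dataclasses
import enum
import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import SCHEMA_VERSION
from .errors import ParameterError, SchemaError

#: Tolerance (s) on the uniform frame spacing 1/frame_rate_hz.
TIME_TOL_S = 1e-6

TRACK_CSV_COLUMNS = ["plate_id", "track_id", "time_s", "x_mm", "y_mm", "state", "speed_mm_s"]
CALCIUM_CSV_COLUMNS = ["trace_id", "time_s", "fluorescence_au"]
FLOAT_FORMAT = "%.12g"


class StateCode(str, enum.Enum):
    """Closed vocabulary of per-frame behavioral states.

    FORWARD runs, REVERSALs and OMEGA_TURNs are the analyzed maneuvers;
    SHALLOW_TURN, PAUSE and OTHER are carried through and grouped as
    "other" in ethograms.
    """

    FORWARD = "FORWARD"
    REVERSAL = "REVERSAL"
    OMEGA_TURN = "OMEGA_TURN"
    SHALLOW_TURN = "SHALLOW_TURN"
    PAUSE = "PAUSE"
    OTHER = "OTHER"


_STATE_VALUES = {s.value for s in StateCode}


@dataclasses.dataclass
class TrackRecord:
    """Per-frame time series for one animal plus assay metadata.

    ``frames`` is a DataFrame with columns ``time_s, x_mm, y_mm, state,
    speed_mm_s``; times are uniform at ``1/frame_rate_hz`` starting at
    ``t0_offset_s`` (seconds after removal from food).
    """

    track_id: str
    plate_id: str
    condition: str
    t0_offset_s: float
    frame_rate_hz: float
    frames: pd.DataFrame
    worm_length_mm: float
    pixel_size_mm: float
    pulse_schedule: list[tuple[float, float]] | None = None
    near_barrier: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ParameterError("frame_rate_hz must be > 0")
        if self.worm_length_mm <= 0:
            raise ParameterError("worm_length_mm must be > 0")
        if self.pixel_size_mm <= 0:
            raise ParameterError("pixel_size_mm must be > 0")
        missing = [c for c in TRACK_CSV_COLUMNS[2:] if c not in self.frames.columns]
        if missing:
            raise SchemaError(f"track {self.track_id}: missing frame columns {missing}")
        if len(self.frames) == 0:
            raise SchemaError(f"track {self.track_id}: empty frame table")
        t = self.frames["time_s"].to_numpy(float)
        dt = 1.0 / self.frame_rate_hz
        bad = np.nonzero(np.abs(np.diff(t) - dt) > TIME_TOL_S)[0]
        if bad.size:
            raise SchemaError(
                f"track {self.track_id}: non-uniform sampling at row {int(bad[0]) + 1} "
                f"(expected spacing {dt:.6g} s)"
            )
        states = self.frames["state"]
        badstate = ~states.isin(_STATE_VALUES)
        if badstate.any():
            row = int(np.nonzero(badstate.to_numpy())[0][0])
            raise SchemaError(
                f"track {self.track_id}: unknown state {states.iloc[row]!r} at row {row}"
            )
        if self.pulse_schedule is not None:
            from .optogenetics import validate_pulse_schedule

            validate_pulse_schedule(self.pulse_schedule)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def start_s(self) -> float:
        return float(self.frames["time_s"].iloc[0])

    @property
    def end_s(self) -> float:
        """End of the last frame interval (frames are half-open [t, t+dt))."""
        return float(self.frames["time_s"].iloc[-1]) + 1.0 / self.frame_rate_hz

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def covers(self, start_s: float, end_s: float, tol: float = TIME_TOL_S) -> bool:
        """True if the track is continuous over the whole [start_s, end_s) window."""
        return self.start_s <= start_s + tol and self.end_s >= end_s - tol

    def states(self) -> np.ndarray:
        return self.frames["state"].to_numpy()


@dataclasses.dataclass
class CalciumTrace:
    """Uniformly sampled fluorescence time series for one neuron recording."""

    trace_id: str
    condition: str
    media_switch_s: float
    frame_rate_hz: float
    samples: pd.DataFrame  # columns: time_s, fluorescence_au

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ParameterError("frame_rate_hz must be > 0")
        if len(self.samples) == 0:
            raise SchemaError(f"trace {self.trace_id}: empty sample table")
        f = self.samples["fluorescence_au"].to_numpy(float)
        bad = ~np.isfinite(f) | (f <= 0)
        if bad.any():
            row = int(np.nonzero(bad)[0][0])
            raise SchemaError(
                f"trace {self.trace_id}: non-positive or non-finite fluorescence at row {row}"
            )
        t = self.samples["time_s"].to_numpy(float)
        dt = 1.0 / self.frame_rate_hz
        bad_t = np.nonzero(np.abs(np.diff(t) - dt) > TIME_TOL_S)[0]
        if bad_t.size:
            raise SchemaError(
                f"trace {self.trace_id}: non-uniform sampling at row {int(bad_t[0]) + 1}"
            )

    @property
    def n_frames(self) -> int:
        return len(self.samples)

    def fluorescence(self) -> np.ndarray:
        return self.samples["fluorescence_au"].to_numpy(float)

    def times(self) -> np.ndarray:
        return self.samples["time_s"].to_numpy(float)


# ---------------------------------------------------------------------------
# track storage


def _track_meta(track: TrackRecord, n_rows: int) -> dict:
    return {
        "track_id": track.track_id,
        "plate_id": track.plate_id,
        "condition": track.condition,
        "t0_offset_s": track.t0_offset_s,
        "frame_rate_hz": track.frame_rate_hz,
        "worm_length_mm": track.worm_length_mm,
        "pixel_size_mm": track.pixel_size_mm,
        "pulse_schedule": track.pulse_schedule,
        "near_barrier": track.near_barrier,
        "n_frames": n_rows,
    }


def write_tracks(tracks: Sequence[TrackRecord], path: str | Path) -> dict:
    """Write tracks as ``tracks.csv`` + ``tracks_meta.json``; return a manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ids = [t.track_id for t in tracks]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise SchemaError(f"duplicate track_id(s): {sorted(dupes)}")

    parts = []
    meta = {"schema_version": SCHEMA_VERSION, "tracks": {}}
    for track in tracks:
        df = track.frames.loc[:, TRACK_CSV_COLUMNS[2:]].copy()
        df.insert(0, "track_id", track.track_id)
        df.insert(0, "plate_id", track.plate_id)
        parts.append(df)
        meta["tracks"][track.track_id] = _track_meta(track, len(df))

    csv_path = path / "tracks.csv"
    if parts:
        pd.concat(parts, ignore_index=True).to_csv(
            csv_path, index=False, float_format=FLOAT_FORMAT
        )
    else:
        pd.DataFrame(columns=TRACK_CSV_COLUMNS).to_csv(csv_path, index=False)
    meta_path = path / "tracks_meta.json"
    meta_path.write_text(json.dumps(meta, indent=1))
    return {
        "files": [csv_path.name, meta_path.name],
        "n_tracks": len(tracks),
        "n_rows": int(sum(len(p) for p in parts)),
    }


def read_tracks(path: str | Path) -> list[TrackRecord]:
    """Read and validate tracks written by :func:`write_tracks`."""
    path = Path(path)
    meta = json.loads((path / "tracks_meta.json").read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {meta.get('schema_version')!r}")
    df = pd.read_csv(path / "tracks.csv", dtype={"plate_id": str, "track_id": str})
    tracks: list[TrackRecord] = []
    for track_id, m in meta["tracks"].items():
        sub = df[df["track_id"] == track_id]
        if len(sub) != m["n_frames"]:
            raise SchemaError(
                f"track {track_id}: {len(sub)} rows in CSV but sidecar says {m['n_frames']}"
            )
        frames = sub.loc[:, TRACK_CSV_COLUMNS[2:]].reset_index(drop=True)
        schedule = m["pulse_schedule"]
        tracks.append(
            TrackRecord(
                track_id=track_id,
                plate_id=m["plate_id"],
                condition=m["condition"],
                t0_offset_s=m["t0_offset_s"],
                frame_rate_hz=m["frame_rate_hz"],
                frames=frames,
                worm_length_mm=m["worm_length_mm"],
                pixel_size_mm=m["pixel_size_mm"],
                pulse_schedule=None if schedule is None else [tuple(p) for p in schedule],
                near_barrier=m.get("near_barrier", False),
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# calcium storage


def write_calcium(traces: Sequence[CalciumTrace], path: str | Path) -> dict:
    """Write traces as ``calcium.csv`` + ``calcium_meta.json``; return a manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ids = [t.trace_id for t in traces]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise SchemaError(f"duplicate trace_id(s): {sorted(dupes)}")
    parts = []
    meta = {"schema_version": SCHEMA_VERSION, "traces": {}}
    for tr in traces:
        df = tr.samples.loc[:, CALCIUM_CSV_COLUMNS[1:]].copy()
        df.insert(0, "trace_id", tr.trace_id)
        parts.append(df)
        meta["traces"][tr.trace_id] = {
            "trace_id": tr.trace_id,
            "condition": tr.condition,
            "media_switch_s": tr.media_switch_s,
            "frame_rate_hz": tr.frame_rate_hz,
            "n_frames": len(df),
        }
    csv_path = path / "calcium.csv"
    if parts:
        pd.concat(parts, ignore_index=True).to_csv(
            csv_path, index=False, float_format=FLOAT_FORMAT
        )
    else:
        pd.DataFrame(columns=CALCIUM_CSV_COLUMNS).to_csv(csv_path, index=False)
    meta_path = path / "calcium_meta.json"
    meta_path.write_text(json.dumps(meta, indent=1))
    return {
        "files": [csv_path.name, meta_path.name],
        "n_traces": len(traces),
        "n_rows": int(sum(len(p) for p in parts)),
    }


def read_calcium(path: str | Path) -> list[CalciumTrace]:
    path = Path(path)
    meta = json.loads((path / "calcium_meta.json").read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {meta.get('schema_version')!r}")
    df = pd.read_csv(path / "calcium.csv", dtype={"trace_id": str})
    traces = []
    for trace_id, m in meta["traces"].items():
        sub = df[df["trace_id"] == trace_id]
        if len(sub) != m["n_frames"]:
            raise SchemaError(
                f"trace {trace_id}: {len(sub)} rows in CSV but sidecar says {m['n_frames']}"
            )
        traces.append(
            CalciumTrace(
                trace_id=trace_id,
                condition=m["condition"],
                media_switch_s=m["media_switch_s"],
                frame_rate_hz=m["frame_rate_hz"],
                samples=sub.loc[:, CALCIUM_CSV_COLUMNS[1:]].reset_index(drop=True),
            )
        )
    return traces
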