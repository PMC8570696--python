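"""ON/OFF state calling for two-state calcium activity traces.

The pipeline mirrors the standard treatment of AVA-type GCaMP recordings:

1. smooth the raw fluorescence with a centered 1 s boxcar;
2. set the baseline F0 to the median of the samples at or below the 10th
   percentile of the smoothed trace, and form dF/F0;
3. traces whose peak dF/F0 never exceeds 10% are non-qualifying and stay
   OFF throughout; qualifying traces get an initial binary assignment (ON
   wherever dF/F0 > 50% of its maximum);
4. compute the time derivative of dF/F0, smooth it over 3 s, and derive
   per-trace rise/fall thresholds as a fraction (default 0.25) of the
   derivative's maximum/minimum;
5. refine each initial ON epoch by extending its start back to the most
   recent upward crossing of the rise threshold and its end forward to the
   end of the fall-threshold excursion, merge overlaps, and drop refined
   epochs shorter than 1 s.

Because F0 is defined from the trace itself, every derived quantity is
invariant to a multiplicative gain on the raw fluorescence.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from . import config
from .errors import ParameterError
from .track_io import CalciumTrace


@dataclasses.dataclass
class CalciumConfig:
    """Tunable parameters of the state-calling pipeline."""

    smooth_s: float = config.CALCIUM_SMOOTH_S
    deriv_smooth_s: float = config.DERIV_SMOOTH_S
    f0_lowest_fraction: float = config.F0_LOWEST_FRACTION
    qualify_dff: float = config.QUALIFY_DFF
    fmax_fraction: float = config.INITIAL_STATE_FMAX_FRACTION
    deriv_threshold_factor: float = config.DERIV_THRESHOLD_FACTOR
    min_epoch_s: float = config.MIN_ON_EPOCH_S
    f0_statistic: str = "median"  # or "mean" of the lowest decile


@dataclasses.dataclass
class ProcessedTrace:
    trace: CalciumTrace
    smoothed_f: np.ndarray
    f0: float
    dff: np.ndarray
    fmax: float
    dfdt: np.ndarray
    qualifies: bool


@dataclasses.dataclass
class StateAnnotation:
    """Frame-wise ON/OFF labels plus the equivalent epoch list."""

    on: np.ndarray  # boolean per frame
    frame_rate_hz: float
    provenance: str  # "initial" or "final"

    def epochs(self) -> list[tuple[str, float, float]]:
        """Alternating (state, start_s, end_s) epochs tiling the trace."""
        on = self.on.astype(bool)
        n = on.size
        if n == 0:
            return []
        change = np.nonzero(on[1:] != on[:-1])[0] + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [n]))
        dt = 1.0 / self.frame_rate_hz
        return [
            ("ON" if on[s] else "OFF", s * dt, e * dt) for s, e in zip(starts, ends)
        ]

    def on_epochs(self) -> list[tuple[float, float]]:
        return [(s, e) for state, s, e in self.epochs() if state == "ON"]


@dataclasses.dataclass
class StateMetrics:
    window: tuple[float, float]
    fraction_on: float
    n_off_to_on: int
    mean_on_duration_s: float


def smooth_boxcar(series: Sequence[float], window_s: float, rate: float) -> np.ndarray:
    """Centered moving average over ``round(window_s * rate)`` frames.

    For an even window length w the window spans w//2 frames to the left
    and w//2 - 1 to the right of the center; at the edges the window is
    truncated and the mean taken over the frames actually present, so the
    output has the input's length and constants pass through unchanged.
    """
    x = np.asarray(series, dtype=float)
    w = int(round(window_s * rate))
    if w < 1:
        raise ParameterError("smoothing window is shorter than one frame")
    if w == 1 or x.size == 0:
        return x.copy()
    left = w // 2
    right = w - 1 - left
    n = x.size
    csum = np.concatenate(([0.0], np.cumsum(x)))
    lo = np.maximum(np.arange(n) - left, 0)
    hi = np.minimum(np.arange(n) + right + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def baseline_f0(smoothed_f: Sequence[float], lowest_fraction: float = config.F0_LOWEST_FRACTION,
                statistic: str = "median") -> float:
    """Baseline = median (or mean) of the lowest ``lowest_fraction`` of samples."""
    x = np.asarray(smoothed_f, dtype=float)
    if x.size < 10:
        raise ParameterError("baseline_f0 requires at least 10 samples")
    cutoff = np.percentile(x, 100.0 * lowest_fraction)
    low = x[x <= cutoff]
    f0 = float(np.median(low) if statistic == "median" else np.mean(low))
    if f0 <= 0:
        raise ParameterError("baseline f0 is non-positive; not a valid fluorescence trace")
    return f0


def smoothed_derivative(
    dff: Sequence[float], rate: float, window_s: float = config.DERIV_SMOOTH_S
) -> np.ndarray:
    """Central-difference time derivative of dF/F0 (1/s), boxcar-smoothed."""
    x = np.asarray(dff, dtype=float)
    if x.size < 2:
        raise ParameterError("derivative requires at least 2 frames")
    ddt = np.gradient(x, 1.0 / rate)
    return smooth_boxcar(ddt, window_s, rate)


def process_trace(trace: CalciumTrace, cfg: CalciumConfig | None = None) -> ProcessedTrace:
    cfg = cfg or CalciumConfig()
    f = trace.fluorescence()
    smoothed = smooth_boxcar(f, cfg.smooth_s, trace.frame_rate_hz)
    f0 = baseline_f0(smoothed, cfg.f0_lowest_fraction, cfg.f0_statistic)
    dff = (smoothed - f0) / f0
    fmax = float(np.max(dff))
    dfdt = smoothed_derivative(dff, trace.frame_rate_hz, cfg.deriv_smooth_s)
    return ProcessedTrace(
        trace=trace,
        smoothed_f=smoothed,
        f0=f0,
        dff=dff,
        fmax=fmax,
        dfdt=dfdt,
        qualifies=fmax > cfg.qualify_dff,
    )


def initial_binary_states(
    processed: ProcessedTrace, cfg: CalciumConfig | None = None
) -> StateAnnotation:
    """All OFF for non-qualifying traces; else ON where dF/F0 > 50% of Fmax."""
    cfg = cfg or CalciumConfig()
    if not processed.qualifies:
        on = np.zeros(processed.dff.size, dtype=bool)
    else:
        on = processed.dff > cfg.fmax_fraction * processed.fmax
    return StateAnnotation(on=on, frame_rate_hz=processed.trace.frame_rate_hz,
                           provenance="initial")


def transition_thresholds(
    dfdt: Sequence[float], factor: float = config.DERIV_THRESHOLD_FACTOR
) -> tuple[float, float]:
    """(rise, fall) thresholds as a fraction of the per-trace dF/dt extrema.

    Returns (0, 0) for a flat derivative (degenerate trace).
    """
    x = np.asarray(dfdt, dtype=float)
    if x.size == 0 or np.all(x == 0):
        return 0.0, 0.0
    return factor * float(np.max(x)), factor * float(np.min(x))


def final_states(
    initial: StateAnnotation,
    dfdt: Sequence[float],
    thresholds: tuple[float, float],
    cfg: CalciumConfig | None = None,
) -> StateAnnotation:
    """Refine initial ON epochs with the derivative thresholds.

    The initial 50%-of-Fmax assignment lags the true transitions by the
    indicator kinetics, so each initial ON epoch's boundaries are moved to
    where the corresponding dF/dt excursion *begins*: the start is walked
    back to the first frame of the rise-threshold excursion (dF/dt >
    rise threshold) containing it, and the end is walked back to the first
    frame of the fall-threshold excursion (dF/dt < fall threshold) that
    contains it -- the moment the decay starts, which marks the OFF
    transition.  Refinement never crosses into neighboring initial ON
    epochs; overlapping refined epochs are merged and refined epochs
    shorter than ``min_epoch_s`` are dropped.
    """
    cfg = cfg or CalciumConfig()
    dfdt = np.asarray(dfdt, dtype=float)
    rise_thr, fall_thr = thresholds
    rate = initial.frame_rate_hz
    on0 = initial.on.astype(bool)
    n = on0.size
    dt = 1.0 / rate

    runs = []
    change = np.nonzero(on0[1:] != on0[:-1])[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    on_runs = [(int(s), int(e)) for s, e in zip(starts, ends) if on0[s]]

    refined = []
    for k, (s, e) in enumerate(on_runs):
        lower = on_runs[k - 1][1] if k > 0 else 0
        new_s = s
        while new_s > lower and dfdt[new_s - 1] > rise_thr:
            new_s -= 1
        new_e = e
        while new_e - 1 > new_s and dfdt[new_e - 1] < fall_thr:
            new_e -= 1
        refined.append((new_s, new_e))

    # merge overlaps, then drop flickers
    merged: list[list[int]] = []
    for s, e in refined:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    min_frames = int(round(cfg.min_epoch_s * rate))
    on = np.zeros(n, dtype=bool)
    for s, e in merged:
        if e - s >= min_frames:
            on[s:e] = True
    return StateAnnotation(on=on, frame_rate_hz=rate, provenance="final")


def state_metrics(annotation: StateAnnotation, window: tuple[float, float]) -> StateMetrics:
    """Fraction ON, OFF->ON transition count, and mean ON duration in a window.

    Transitions and epoch durations are attributed to the window their ON
    onset falls in.
    """
    start_s, end_s = window
    n = annotation.on.size
    dt = 1.0 / annotation.frame_rate_hz
    if start_s < -1e-9 or end_s > n * dt + 1e-9 or end_s <= start_s:
        raise ParameterError("window outside the annotated trace")
    i0 = int(round(start_s * annotation.frame_rate_hz))
    i1 = int(round(end_s * annotation.frame_rate_hz))
    frac = float(np.mean(annotation.on[i0:i1]))
    onsets = [
        (s, e) for s, e in annotation.on_epochs() if start_s <= s < end_s and s > 0
    ]
    durations = [e - s for s, e in onsets]
    return StateMetrics(
        window=window,
        fraction_on=frac,
        n_off_to_on=len(onsets),
        mean_on_duration_s=float(np.mean(durations)) if durations else 0.0,
    )


def call_states(
    trace: CalciumTrace,
    cfg: CalciumConfig | None = None,
    windows: Sequence[tuple[float, float]] | None = None,
) -> tuple[ProcessedTrace, StateAnnotation, list[StateMetrics]]:
    """Full deterministic pipeline: smooth -> F0 -> dF/F0 -> initial -> final.

    ``windows`` are (start_s, end_s) pairs in trace time; defaults to the
    local/global search windows relative to the conditioned-media switch.
    """
    cfg = cfg or CalciumConfig()
    processed = process_trace(trace, cfg)
    initial = initial_binary_states(processed, cfg)
    thresholds = transition_thresholds(processed.dfdt, cfg.deriv_threshold_factor)
    final = final_states(initial, processed.dfdt, thresholds, cfg)
    if windows is None:
        t_end = trace.n_frames / trace.frame_rate_hz
        windows = []
        for rel_start, rel_end in (config.CALCIUM_LOCAL_WINDOW_S, config.CALCIUM_GLOBAL_WINDOW_S):
            w = (trace.media_switch_s + rel_start, trace.media_switch_s + rel_end)
            if w[1] <= t_end + 1e-9:
                windows.append(w)
    metrics = [state_metrics(final, w) for w in windows]
    return processed, final, metrics
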