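"""Synthetic foraging tracks, optogenetic experiments, and calcium traces.

The generator exists so that every downstream analysis stage can be tested
against planted ground truth without any recorded data.  Behavior is modeled
as a semi-Markov process: forward runs are terminated by a time-varying
reversal hazard that holds at a high local-search rate and then decays
exponentially toward a low global-search rate; reversal path lengths come
from a two-component (short/long) lognormal mixture; each reversal is
followed by an omega turn with a probability that is logistic in its length;
pauses interrupt forward runs as an independent Poisson process.  The
centroid path moves forward with angular diffusion, retraces straight
backward during reversals, and reorients by a large planted angle across
omega turns.

The planted hazard is calibrated as the *observed wall-clock onset rate*:
because the hazard only runs during forward movement, the generator inflates
the forward-state hazard by the renewal correction
``lambda / (1 - lambda * E[dead time per maneuver] - pause duty)`` so that a
planted rate of, say, 3.5 reversals/min is what a frequency analysis of the
output actually measures (exact in expectation for a constant hazard).

Two-state calcium traces are an exact continuous-time telegraph process
sampled at the frame rate, passed through first-order rise/decay indicator
kinetics, with optional linear bleaching and Gaussian noise.
"""
from __future__ import annotations

import dataclasses
import math
import zlib
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, ScheduleError
from .track_io import CalciumTrace, StateCode, TrackRecord

__all__ = [
    "LognormalMixture",
    "ForagingSimParams",
    "OptoSimParams",
    "CalciumSimParams",
    "TruthEvent",
    "GroundTruth",
    "simulate_foraging_track",
    "simulate_plate",
    "simulate_opto_track",
    "simulate_calcium_trace",
    "child_seed_sequence",
    "hazard_per_min",
    "mean_coupling_probability",
    "mean_maneuver_dead_time_s",
]


@dataclasses.dataclass(frozen=True)
class LognormalMixture:
    """Mixture of lognormal components, used for reversal path lengths (bl).

    Defaults put 60% of mass in a short component (median 0.25 bl) and 40%
    in a long component (median 1.5 bl), cleanly separated by the 0.5 bl
    short/long class boundary.
    """

    weights: tuple[float, ...] = (0.6, 0.4)
    mu_log: tuple[float, ...] = (math.log(0.25), math.log(1.5))
    sigma_log: tuple[float, ...] = (0.3, 0.3)

    def validate(self) -> None:
        if len(self.weights) != len(self.mu_log) or len(self.weights) != len(self.sigma_log):
            raise ParameterError("rev_length_mixture: component arrays differ in length")
        if any(w < 0 for w in self.weights):
            raise ParameterError("rev_length_mixture.weights must be >= 0")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ParameterError("rev_length_mixture.weights must sum to 1")
        if any(s <= 0 for s in self.sigma_log):
            raise ParameterError("rev_length_mixture.sigma_log must be > 0")

    def mean(self) -> float:
        return sum(
            w * math.exp(m + s * s / 2.0)
            for w, m, s in zip(self.weights, self.mu_log, self.sigma_log)
        )

    def sample(self, rng: np.random.Generator) -> tuple[float, int]:
        k = int(rng.choice(len(self.weights), p=self.weights))
        return float(rng.lognormal(self.mu_log[k], self.sigma_log[k])), k


@dataclasses.dataclass
class ForagingSimParams:
    """Parameters of the foraging-track generator.

    Rates (``lambda_local``, ``lambda_global``, ``pause_rate``) are in
    events per minute of wall-clock time; speeds in mm/s; lengths in body
    lengths (bl).  The hazard holds at ``lambda_local`` until
    ``hazard_hold_s`` and then relaxes exponentially toward
    ``lambda_global`` with time constant ``tau_decay_s``, emulating the
    local-to-global search transition over the first tens of minutes off
    food.
    """

    frame_rate_hz: float = 3.0
    duration_s: float = 2700.0
    lambda_local: float = 3.5
    lambda_global: float = 0.8
    hazard_hold_s: float = 480.0
    tau_decay_s: float = 420.0
    rev_length_mixture: LognormalMixture = dataclasses.field(default_factory=LognormalMixture)
    rev_speed_mean: float = 0.18
    fwd_speed_mean: float = 0.15
    speed_noise_frac: float = 0.1
    omega_coupling_slope: float = 4.0
    omega_coupling_midpoint_bl: float = 0.6
    omega_duration_s: float = 1.5
    pause_rate: float = 0.5
    pause_duration_s: float = 1.0
    heading_diffusion_rad_per_s: float = 0.3
    worm_length_mm: float = 1.0
    pixel_size_mm: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ParameterError("frame_rate_hz must be > 0")
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be > 0")
        for field in ("lambda_local", "lambda_global", "pause_rate"):
            if getattr(self, field) < 0:
                raise ParameterError(f"{field} must be >= 0")
        if self.lambda_local < self.lambda_global:
            raise ParameterError("lambda_local must be >= lambda_global")
        if self.tau_decay_s <= 0:
            raise ParameterError("tau_decay_s must be > 0")
        if self.rev_speed_mean <= 0 or self.fwd_speed_mean < 0:
            raise ParameterError("rev_speed_mean must be > 0 and fwd_speed_mean >= 0")
        if self.worm_length_mm <= 0:
            raise ParameterError("worm_length_mm must be > 0")
        if self.pixel_size_mm <= 0:
            raise ParameterError("pixel_size_mm must be > 0")
        if self.omega_duration_s <= 0 or self.pause_duration_s <= 0:
            raise ParameterError("omega_duration_s and pause_duration_s must be > 0")
        self.rev_length_mixture.validate()


def default_pulse_schedule(
    n_pulses: int = 3,
    first_onset_s: float = 600.0,
    pulse_s: float = 20.0,
    interpulse_s: float = 100.0,
) -> list[tuple[float, float]]:
    """n pulses of ``pulse_s`` seconds separated by ``interpulse_s`` gaps."""
    period = pulse_s + interpulse_s
    return [(first_onset_s + i * period, pulse_s) for i in range(n_pulses)]


@dataclasses.dataclass
class OptoSimParams:
    """Foraging simulation plus a light-pulse schedule and hazard boost.

    ``hazard_boost`` multiplies the instantaneous reversal hazard inside
    pulses, but only when ``retinal`` is true (without the retinal cofactor
    the channelrhodopsin is inert, so the light has no effect and the
    output is bit-identical to the base simulation under the same seed).
    """

    base: ForagingSimParams = dataclasses.field(default_factory=ForagingSimParams)
    pulse_schedule: list[tuple[float, float]] = dataclasses.field(
        default_factory=default_pulse_schedule
    )
    hazard_boost: float = 3.0
    retinal: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.hazard_boost < 1.0:
            raise ParameterError("hazard_boost must be >= 1")
        sched = sorted(self.pulse_schedule)
        for onset, dur in sched:
            if dur <= 0:
                raise ScheduleError(f"pulse at {onset} s has non-positive duration")
            if onset < 0 or onset + dur > self.base.duration_s:
                raise ScheduleError(f"pulse at {onset} s extends outside the recording")
        for (o1, d1), (o2, _) in zip(sched, sched[1:]):
            if o2 < o1 + d1:
                raise ScheduleError(f"pulses at {o1} s and {o2} s overlap")


@dataclasses.dataclass
class CalciumSimParams:
    """Parameters of the two-state telegraph calcium-trace generator.

    ``on_rate``/``off_rate`` are the OFF->ON and ON->OFF transition rates
    (1/s), so the stationary ON fraction is ``on_rate/(on_rate+off_rate)``
    (0.4 by default, with a mean ON epoch of 20 s).  ``amplitude_frac`` is
    the fractional fluorescence increase of the ON state; with the default
    noise of 0.2 x baseline the trace SNR is ~5.
    """

    frame_rate_hz: float = 10.0
    duration_s: float = 2400.0
    on_rate: float = 1.0 / 30.0
    off_rate: float = 1.0 / 20.0
    f_base: float = 100.0
    amplitude_frac: float = 1.0
    rise_tau_s: float = 0.5
    decay_tau_s: float = 2.0
    noise_sd_frac: float = 0.2
    bleach_frac_per_min: float = 0.0
    media_switch_s: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ParameterError("frame_rate_hz must be > 0")
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be > 0")
        if self.on_rate <= 0 or self.off_rate <= 0:
            raise ParameterError("on_rate and off_rate must be > 0")
        if self.f_base <= 0:
            raise ParameterError("f_base must be > 0")
        if self.amplitude_frac < 0:
            raise ParameterError("amplitude_frac must be >= 0")
        if self.rise_tau_s < 0 or self.decay_tau_s < 0:
            raise ParameterError("rise_tau_s and decay_tau_s must be >= 0")
        if self.noise_sd_frac < 0:
            raise ParameterError("noise_sd_frac must be >= 0")


@dataclasses.dataclass
class TruthEvent:
    """One planted event interval with its generative parameters."""

    kind: str
    start_s: float
    end_s: float
    length_bl: float | None = None
    coupled: bool | None = None
    reorientation_deg: float | None = None

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclasses.dataclass
class GroundTruth:
    """Planted truth for one simulated track or trace.

    ``events`` tile [0, duration] with no gaps or overlaps (tracks);
    ``frame_labels`` is the frame-wise true ON/OFF state (calcium);
    ``hazard`` records the planted hazard timecourse parameters.
    """

    events: list[TruthEvent] = dataclasses.field(default_factory=list)
    frame_labels: np.ndarray | None = None
    hazard: dict | None = None

    def reversal_onsets(self) -> np.ndarray:
        return np.array(
            [e.start_s for e in self.events if e.kind == StateCode.REVERSAL.value]
        )

    def occupancy_fraction(self, kind: str, start_s: float, end_s: float) -> float:
        """Fraction of [start_s, end_s) covered by events of ``kind``."""
        total = 0.0
        for e in self.events:
            if e.kind != kind:
                continue
            total += max(0.0, min(e.end_s, end_s) - max(e.start_s, start_s))
        return total / (end_s - start_s)


# ---------------------------------------------------------------------------
# hazard machinery


def hazard_per_min(params: ForagingSimParams, t: float | np.ndarray) -> float | np.ndarray:
    """Planted reversal-onset rate (events/min of wall-clock time) at time t."""
    lam_l, lam_g = params.lambda_local, params.lambda_global
    hold, tau = params.hazard_hold_s, params.tau_decay_s
    t = np.asarray(t, dtype=float)
    decayed = lam_g + (lam_l - lam_g) * np.exp(-np.maximum(t - hold, 0.0) / tau)
    out = np.where(t < hold, lam_l, decayed)
    return float(out) if out.ndim == 0 else out


def mean_coupling_probability(params: ForagingSimParams) -> float:
    """E[P(omega | reversal length)] under the planted length mixture.

    Gauss-Hermite quadrature over each lognormal component; used for the
    dead-time renewal correction, not per-sample.
    """
    nodes, weights = np.polynomial.hermite.hermgauss(40)
    mix = params.rev_length_mixture
    total = 0.0
    for w, mu, sigma in zip(mix.weights, mix.mu_log, mix.sigma_log):
        lengths = np.exp(mu + math.sqrt(2.0) * sigma * nodes)
        p = 1.0 / (
            1.0
            + np.exp(
                -params.omega_coupling_slope * (lengths - params.omega_coupling_midpoint_bl)
            )
        )
        total += w * float(np.sum(weights * p)) / math.sqrt(math.pi)
    return total


def mean_maneuver_dead_time_s(params: ForagingSimParams) -> float:
    """Expected non-forward time per reversal maneuver (reversal + omega)."""
    mean_rev_s = params.rev_length_mixture.mean() * params.worm_length_mm / params.rev_speed_mean
    dt = 1.0 / params.frame_rate_hz
    omega_s = max(1, round(params.omega_duration_s * params.frame_rate_hz)) * dt
    return mean_rev_s + mean_coupling_probability(params) * omega_s


def _adjusted_hazard_per_s(params: ForagingSimParams) -> Callable[[float], float]:
    """Forward-state hazard (1/s) whose observed onset rate equals the plant.

    Renewal correction: observed rate = hazard x P(forward), so the hazard
    is divided by (1 - lambda*E[dead] - pause duty), clamped away from 0.
    """
    e_dead = mean_maneuver_dead_time_s(params)
    pause_duty = (params.pause_rate / 60.0) * params.pause_duration_s

    def adjusted(t: float) -> float:
        lam_s = hazard_per_min(params, t) / 60.0
        loss = min(0.9, lam_s * e_dead + pause_duty)
        return lam_s / (1.0 - loss)

    return adjusted


def child_seed_sequence(master_seed: int, plate_id: str, index: int) -> np.random.SeedSequence:
    """Deterministic per-track seed: master seed hashed with (plate_id, index)."""
    plate_hash = zlib.crc32(str(plate_id).encode("utf-8"))
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, plate_hash, int(index)])


# ---------------------------------------------------------------------------
# foraging track generation


def _snap_frames(duration_s: float, rate: float) -> int:
    return max(1, int(round(duration_s * rate)))


def _simulate_track_core(
    params: ForagingSimParams,
    boost_of_t: Callable[[float], float],
    max_boost: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[TruthEvent]]:
    """Event-list generation + frame synthesis shared by the plain and opto paths."""
    rate = params.frame_rate_hz
    dt = 1.0 / rate
    n_total = int(round(params.duration_s * rate))
    hazard = _adjusted_hazard_per_s(params)
    bound = hazard(0.0) * max_boost  # hazard is maximal at t=0 (monotone decay)
    pause_rate_s = params.pause_rate / 60.0
    mix = params.rev_length_mixture
    worm = params.worm_length_mm

    # --- event list, durations in whole frames -----------------------------
    events: list[tuple[str, int, dict]] = []
    frame = 0
    while frame < n_total:
        t0 = frame * dt
        # waiting time to next reversal onset, by thinning against `bound`
        if bound > 0:
            w_rev = 0.0
            while True:
                w_rev += rng.exponential(1.0 / bound)
                t_prop = t0 + w_rev
                if t_prop * rate >= n_total:
                    w_rev = math.inf
                    break
                if rng.uniform() * bound < hazard(t_prop) * boost_of_t(t_prop):
                    break
        else:
            w_rev = math.inf
        w_pause = rng.exponential(1.0 / pause_rate_s) if pause_rate_s > 0 else math.inf
        wait = min(w_rev, w_pause)

        if not math.isfinite(wait) or frame + _snap_frames(wait, rate) >= n_total:
            events.append((StateCode.FORWARD.value, n_total - frame, {}))
            frame = n_total
            break
        n_fwd = _snap_frames(wait, rate)
        events.append((StateCode.FORWARD.value, n_fwd, {}))
        frame += n_fwd

        if w_pause < w_rev:
            n_p = min(_snap_frames(params.pause_duration_s, rate), n_total - frame)
            if n_p > 0:
                events.append((StateCode.PAUSE.value, n_p, {}))
                frame += n_p
            continue

        length_bl, component = mix.sample(rng)
        coupled = rng.uniform() < 1.0 / (
            1.0
            + math.exp(
                -params.omega_coupling_slope * (length_bl - params.omega_coupling_midpoint_bl)
            )
        )
        n_rev = min(
            _snap_frames(length_bl * worm / params.rev_speed_mean, rate), n_total - frame
        )
        if n_rev > 0:
            events.append(
                (
                    StateCode.REVERSAL.value,
                    n_rev,
                    {"length_bl": length_bl, "coupled": coupled, "component": component},
                )
            )
            frame += n_rev
        if coupled and frame < n_total:
            sign = 1.0 if rng.uniform() < 0.5 else -1.0
            delta_deg = sign * rng.uniform(120.0, 180.0)
            n_om = min(_snap_frames(params.omega_duration_s, rate), n_total - frame)
            if n_om > 0:
                events.append(
                    (StateCode.OMEGA_TURN.value, n_om, {"reorientation_deg": delta_deg})
                )
                frame += n_om

    # --- frame synthesis ---------------------------------------------------
    times = np.arange(n_total) / rate
    speeds = np.zeros(n_total)
    x = np.zeros(n_total + 1)
    y = np.zeros(n_total + 1)
    heading = rng.uniform(0.0, 2.0 * math.pi)
    sigma_step = params.heading_diffusion_rad_per_s * math.sqrt(dt)

    truth: list[TruthEvent] = []
    i = 0
    for kind, n, extra in events:
        start_s, end_s = i * dt, (i + n) * dt
        if kind == StateCode.FORWARD.value:
            dtheta = rng.normal(0.0, sigma_step, size=n) if sigma_step > 0 else np.zeros(n)
            headings = heading + np.cumsum(dtheta)
            noise = 1.0 + params.speed_noise_frac * rng.normal(size=n)
            sp = params.fwd_speed_mean * np.clip(noise, 0.0, None)
            step = sp * dt
            x[i + 1 : i + n + 1] = x[i] + np.cumsum(step * np.cos(headings))
            y[i + 1 : i + n + 1] = y[i] + np.cumsum(step * np.sin(headings))
            speeds[i : i + n] = sp
            heading = float(headings[-1])
            truth.append(TruthEvent(kind, start_s, end_s))
        elif kind == StateCode.PAUSE.value:
            x[i + 1 : i + n + 1] = x[i]
            y[i + 1 : i + n + 1] = y[i]
            truth.append(TruthEvent(kind, start_s, end_s))
        elif kind == StateCode.REVERSAL.value:
            # per-frame increments jittered but renormalized so the summed
            # path equals the planted length exactly
            u = np.clip(1.0 + params.speed_noise_frac * rng.normal(size=n), 0.1, None)
            inc = u / u.sum() * extra["length_bl"] * worm
            back = heading + math.pi
            x[i + 1 : i + n + 1] = x[i] + np.cumsum(inc * math.cos(back))
            y[i + 1 : i + n + 1] = y[i] + np.cumsum(inc * math.sin(back))
            speeds[i : i + n] = inc * rate
            truth.append(
                TruthEvent(
                    kind, start_s, end_s,
                    length_bl=extra["length_bl"], coupled=extra["coupled"],
                )
            )
        elif kind == StateCode.OMEGA_TURN.value:
            delta = math.radians(extra["reorientation_deg"])
            new_heading = heading + delta
            wiggle = 0.01  # mm per frame; omegas are nearly in-place
            x[i + 1 : i + n + 1] = x[i] + np.cumsum(
                np.full(n, wiggle * math.cos(new_heading))
            )
            y[i + 1 : i + n + 1] = y[i] + np.cumsum(
                np.full(n, wiggle * math.sin(new_heading))
            )
            speeds[i : i + n] = wiggle * rate
            heading = new_heading
            truth.append(
                TruthEvent(kind, start_s, end_s, reorientation_deg=extra["reorientation_deg"])
            )
        i += n

    frames = pd.DataFrame(
        {
            "time_s": times,
            "x_mm": x[:n_total],
            "y_mm": y[:n_total],
            "state": states_from_events(events, n_total),
            "speed_mm_s": speeds,
        }
    )
    return frames, truth


def states_from_events(events: list[tuple[str, int, dict]], n_total: int) -> np.ndarray:
    out = np.empty(n_total, dtype=object)
    i = 0
    for kind, n, _ in events:
        out[i : i + n] = kind
        i += n
    return out


def simulate_foraging_track(
    params: ForagingSimParams,
    track_id: str = "track000",
    plate_id: str = "plate000",
    condition: str = "simulated",
    seed_seq: np.random.SeedSequence | None = None,
) -> tuple[TrackRecord, GroundTruth]:
    """Simulate one foraging track; see the module docstring for the model."""
    params.validate()
    rng = np.random.Generator(
        np.random.PCG64(seed_seq if seed_seq is not None else np.random.SeedSequence(params.seed))
    )
    frames, truth = _simulate_track_core(params, lambda t: 1.0, 1.0, rng)
    track = TrackRecord(
        track_id=track_id,
        plate_id=plate_id,
        condition=condition,
        t0_offset_s=0.0,
        frame_rate_hz=params.frame_rate_hz,
        frames=frames,
        worm_length_mm=params.worm_length_mm,
        pixel_size_mm=params.pixel_size_mm,
    )
    gt = GroundTruth(
        events=truth,
        hazard={
            "lambda_local": params.lambda_local,
            "lambda_global": params.lambda_global,
            "hazard_hold_s": params.hazard_hold_s,
            "tau_decay_s": params.tau_decay_s,
        },
    )
    return track, gt


def simulate_plate(
    params: ForagingSimParams,
    n_animals: int,
    plate_id: str = "plate000",
    condition: str = "simulated",
    return_truth: bool = False,
):
    """Simulate ``n_animals`` independent tracks sharing one plate.

    Per-track seeds are derived deterministically from ``params.seed`` and
    (plate_id, track index), so plates can be generated in any order or in
    parallel with identical results.
    """
    if n_animals < 1:
        raise ParameterError("n_animals must be >= 1")
    tracks, truths = [], []
    for i in range(n_animals):
        track, gt = simulate_foraging_track(
            params,
            track_id=f"{plate_id}_t{i:03d}",
            plate_id=plate_id,
            condition=condition,
            seed_seq=child_seed_sequence(params.seed, plate_id, i),
        )
        tracks.append(track)
        truths.append(gt)
    return (tracks, truths) if return_truth else tracks


def simulate_opto_track(
    params: OptoSimParams,
    track_id: str = "track000",
    plate_id: str = "plate000",
    condition: str = "opto",
    seed_seq: np.random.SeedSequence | None = None,
) -> tuple[TrackRecord, GroundTruth]:
    """Simulate a track whose reversal hazard is boosted during light pulses.

    With ``retinal=False`` the boost is inert and the output is identical
    to :func:`simulate_foraging_track` under the same seed.
    """
    params.validate()
    base = params.base
    rng = np.random.Generator(
        np.random.PCG64(seed_seq if seed_seq is not None else np.random.SeedSequence(base.seed))
    )
    schedule = sorted(params.pulse_schedule)
    boost = params.hazard_boost if params.retinal else 1.0

    if boost == 1.0:
        boost_of_t: Callable[[float], float] = lambda t: 1.0
    else:
        onsets = np.array([p[0] for p in schedule])
        ends = np.array([p[0] + p[1] for p in schedule])

        def boost_of_t(t: float) -> float:
            j = int(np.searchsorted(onsets, t, side="right")) - 1
            return boost if j >= 0 and t < ends[j] else 1.0

    frames, truth = _simulate_track_core(base, boost_of_t, boost, rng)
    track = TrackRecord(
        track_id=track_id,
        plate_id=plate_id,
        condition=condition,
        t0_offset_s=0.0,
        frame_rate_hz=base.frame_rate_hz,
        frames=frames,
        worm_length_mm=base.worm_length_mm,
        pixel_size_mm=base.pixel_size_mm,
        pulse_schedule=[tuple(p) for p in schedule],
    )
    gt = GroundTruth(
        events=truth,
        hazard={
            "lambda_local": base.lambda_local,
            "lambda_global": base.lambda_global,
            "hazard_hold_s": base.hazard_hold_s,
            "tau_decay_s": base.tau_decay_s,
            "hazard_boost": boost,
            "pulse_schedule": [list(p) for p in schedule],
        },
    )
    return track, gt


# ---------------------------------------------------------------------------
# calcium traces


def simulate_calcium_trace(
    params: CalciumSimParams,
    trace_id: str = "trace000",
    condition: str = "simulated",
    seed_seq: np.random.SeedSequence | None = None,
) -> tuple[CalciumTrace, GroundTruth]:
    """Simulate one two-state telegraph calcium trace with indicator kinetics."""
    params.validate()
    rng = np.random.Generator(
        np.random.PCG64(seed_seq if seed_seq is not None else np.random.SeedSequence(params.seed))
    )
    rate, dur = params.frame_rate_hz, params.duration_s
    n = int(round(dur * rate))
    dt = 1.0 / rate

    # exact continuous-time telegraph, initialized at stationarity
    p_on = params.on_rate / (params.on_rate + params.off_rate)
    state = 1 if rng.uniform() < p_on else 0
    t = 0.0
    epochs: list[TruthEvent] = []
    switch_times: list[float] = []
    switch_states: list[int] = [state]
    while t < dur:
        rate_out = params.off_rate if state else params.on_rate
        sojourn = rng.exponential(1.0 / rate_out)
        epochs.append(TruthEvent("ON" if state else "OFF", t, min(t + sojourn, dur)))
        t += sojourn
        if t < dur:
            switch_times.append(t)
            state = 1 - state
            switch_states.append(state)

    times = np.arange(n) / rate
    idx = np.searchsorted(np.array(switch_times), times, side="right")
    labels = np.array(switch_states, dtype=int)[idx]

    # first-order rise/decay kinetics (tau 0 => instantaneous)
    c = np.empty(n)
    c[0] = float(labels[0])
    a_rise = 1.0 if params.rise_tau_s == 0 else 1.0 - math.exp(-dt / params.rise_tau_s)
    a_decay = 1.0 if params.decay_tau_s == 0 else 1.0 - math.exp(-dt / params.decay_tau_s)
    for i in range(1, n):
        a = a_rise if labels[i] else a_decay
        c[i] = c[i - 1] + (labels[i] - c[i - 1]) * a

    f = params.f_base * (1.0 + params.amplitude_frac * c)
    if params.bleach_frac_per_min:
        f = f * (1.0 - params.bleach_frac_per_min * times / 60.0)
    if params.noise_sd_frac > 0:
        f = f + rng.normal(0.0, params.noise_sd_frac * params.f_base, size=n)
    f = np.maximum(f, params.f_base * 1e-3)  # keep fluorescence physical

    trace = CalciumTrace(
        trace_id=trace_id,
        condition=condition,
        media_switch_s=params.media_switch_s,
        frame_rate_hz=rate,
        samples=pd.DataFrame({"time_s": times, "fluorescence_au": f}),
    )
    gt = GroundTruth(events=epochs, frame_labels=labels.astype(bool))
    return trace, gt
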