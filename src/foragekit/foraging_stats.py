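"""Windowed frequency statistics, plate aggregation, and KS effect-size tests.

Event frequencies are counted by event onset inside half-open analysis
windows (local search: 4-8 min, global search: 36-40 min after removal from
food) and only for tracks that cover the whole window; per-track
frequencies are averaged within an assay plate, and the plate means are the
statistical unit for group comparisons (Mann-Whitney for two groups,
Kruskal-Wallis with Dunn's post hoc against a control for more).
Distributions of per-event parameters are compared with the two-sample
Kolmogorov-Smirnov test: Bonferroni-adjusted p-values plus the D statistic
as effect size, with D >= 0.15 required for a significant comparison to be
flagged discussable.
"""
from __future__ import annotations

import dataclasses
import enum
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.distributions.empirical_distribution import ECDF as _SMECDF

from . import config
from .errors import ParameterError
from .ethogram import BehaviorEvent, segment_events
from .track_io import StateCode, TrackRecord


class WindowName(str, enum.Enum):
    LOCAL_SEARCH = "LOCAL_SEARCH"
    GLOBAL_SEARCH = "GLOBAL_SEARCH"
    CUSTOM = "CUSTOM"


@dataclasses.dataclass(frozen=True)
class AnalysisWindow:
    """Half-open [start_s, end_s) analysis window."""

    name: WindowName
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ParameterError("window end_s must exceed start_s")

    @property
    def minutes(self) -> float:
        return (self.end_s - self.start_s) / 60.0

    @classmethod
    def local_search(cls) -> "AnalysisWindow":
        return cls(WindowName.LOCAL_SEARCH, *config.LOCAL_WINDOW_S)

    @classmethod
    def global_search(cls) -> "AnalysisWindow":
        return cls(WindowName.GLOBAL_SEARCH, *config.GLOBAL_WINDOW_S)

    @classmethod
    def custom(cls, start_s: float, end_s: float) -> "AnalysisWindow":
        return cls(WindowName.CUSTOM, start_s, end_s)


@dataclasses.dataclass
class FrequencyResult:
    plate_id: str
    condition: str
    window: AnalysisWindow
    events_per_min: float
    n_tracks_used: int


@dataclasses.dataclass
class DistributionComparison:
    """Two-sample KS comparison with Bonferroni adjustment and effect size."""

    sample_a_label: str
    sample_b_label: str
    n_a: int
    n_b: int
    D: float
    p_raw: float
    p_adjusted: float
    n_comparisons: int
    alpha: float
    effect_cutoff: float

    @property
    def discussable(self) -> bool:
        return self.p_adjusted < self.alpha and self.D >= self.effect_cutoff


def window_event_frequency(
    track: TrackRecord,
    events: Sequence[BehaviorEvent],
    window: AnalysisWindow,
    event_kind: str = StateCode.REVERSAL.value,
) -> float | None:
    """Events of ``event_kind`` starting in the window, per minute.

    Returns None ("ineligible") unless the track continuously covers the
    entire window.
    """
    if not track.covers(window.start_s, window.end_s):
        return None
    count = sum(
        1
        for ev in events
        if ev.kind == event_kind and window.start_s <= ev.start_s < window.end_s
    )
    return count / window.minutes


def plate_mean_frequencies(
    tracks: Sequence[TrackRecord],
    events_by_track: Mapping[str, Sequence[BehaviorEvent]],
    window: AnalysisWindow,
    event_kind: str = StateCode.REVERSAL.value,
) -> list[FrequencyResult]:
    """Average eligible per-track frequencies within each plate."""
    per_plate: dict[str, list[float]] = {}
    condition_of: dict[str, str] = {}
    for track in tracks:
        freq = window_event_frequency(
            track, events_by_track[track.track_id], window, event_kind
        )
        if freq is None:
            continue
        per_plate.setdefault(track.plate_id, []).append(freq)
        condition_of[track.plate_id] = track.condition
    results = []
    seen_plates = {t.plate_id for t in tracks}
    for plate_id in sorted(seen_plates):
        vals = per_plate.get(plate_id)
        if not vals:
            warnings.warn(f"plate {plate_id}: no eligible tracks for {window.name.value}")
            continue
        results.append(
            FrequencyResult(
                plate_id=plate_id,
                condition=condition_of[plate_id],
                window=window,
                events_per_min=float(np.mean(vals)),
                n_tracks_used=len(vals),
            )
        )
    return results


def frequency_timecourse(
    tracks: Sequence[TrackRecord],
    events_by_track: Mapping[str, Sequence[BehaviorEvent]],
    bin_s: float = 60.0,
    event_kind: str = StateCode.REVERSAL.value,
) -> pd.DataFrame:
    """Mean +/- SEM event frequency per time bin across eligible tracks.

    A track contributes to a bin only if it covers that bin continuously.
    Returns a DataFrame with columns bin_start_s, mean_per_min, sem_per_min,
    n_tracks.
    """
    if not tracks:
        raise ParameterError("no tracks given")
    t_max = max(t.end_s for t in tracks)
    n_bins = int(math.ceil(t_max / bin_s - 1e-9))
    rows = []
    for b in range(n_bins):
        window = AnalysisWindow.custom(b * bin_s, (b + 1) * bin_s)
        vals = [
            f
            for t in tracks
            if (f := window_event_frequency(t, events_by_track[t.track_id], window, event_kind))
            is not None
        ]
        if not vals:
            continue
        if len(vals) == 1:
            warnings.warn(f"bin starting {window.start_s} s: single track, SEM set to 0")
            sem = 0.0
        else:
            sem = float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
        rows.append(
            {
                "bin_start_s": window.start_s,
                "mean_per_min": float(np.mean(vals)),
                "sem_per_min": sem,
                "n_tracks": len(vals),
            }
        )
    return pd.DataFrame(rows)


def apply_track_exclusions(
    tracks: Sequence[TrackRecord],
    events_by_track: Mapping[str, Sequence[BehaviorEvent]],
    min_track_s: float = config.MIN_TRACK_S,
) -> list[TrackRecord]:
    """Filter tracks for reversal / forward-run parameter analyses.

    Drops tracks shorter than ``min_track_s``, tracks flagged as
    approaching the arena barrier, and tracks without at least one complete
    reversal or complete forward run (complete = not clipped by either
    track boundary).
    """
    kept = []
    for track in tracks:
        if track.duration_s < min_track_s - 1e-9 or track.near_barrier:
            continue
        events = events_by_track[track.track_id]
        has_complete = any(
            ev.kind in (StateCode.REVERSAL.value, StateCode.FORWARD.value)
            and ev.start_s > track.start_s + 1e-9
            and ev.end_s < track.end_s - 1e-9
            for ev in events
        )
        if has_complete:
            kept.append(track)
    return kept


class Ecdf:
    """Right-continuous empirical CDF, evaluable at arbitrary points."""

    def __init__(self, values: Sequence[float]):
        arr = np.asarray(values, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size == 0:
            raise ParameterError("ecdf requires at least one finite value")
        self._fn = _SMECDF(arr)
        self.n = arr.size
        self.values = np.sort(arr)

    def __call__(self, x) -> np.ndarray | float:
        return self._fn(x)

    def step_table(self) -> pd.DataFrame:
        xs = np.unique(self.values)
        return pd.DataFrame({"x": xs, "F": self._fn(xs)})


def ecdf(values: Sequence[float]) -> Ecdf:
    return Ecdf(values)


def ks_compare(
    a: Sequence[float],
    b: Sequence[float],
    n_comparisons: int,
    alpha: float = config.ALPHA,
    effect_cutoff: float = config.KS_EFFECT_CUTOFF,
    label_a: str = "a",
    label_b: str = "b",
    method: str = "asymp",
) -> DistributionComparison:
    """Two-sample KS test with Bonferroni adjustment and D effect size.

    The D statistic is the exact maximum ECDF gap over the pooled sample
    points; ``method`` selects the asymptotic p-value (default) or the
    exact small-sample null distribution (``"exact"``).  The 0.15
    discussability cutoff is a reporting flag, never a filter.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("ks_compare requires two non-empty samples")
    if n_comparisons < 1:
        raise ParameterError("n_comparisons must be >= 1")
    res = sps.ks_2samp(a, b, alternative="two-sided", method=method)
    p_adj = min(1.0, float(res.pvalue) * n_comparisons)
    return DistributionComparison(
        sample_a_label=label_a,
        sample_b_label=label_b,
        n_a=a.size,
        n_b=b.size,
        D=float(res.statistic),
        p_raw=float(res.pvalue),
        p_adjusted=p_adj,
        n_comparisons=n_comparisons,
        alpha=alpha,
        effect_cutoff=effect_cutoff,
    )


def _dunns_test(
    groups: Mapping[str, np.ndarray], control: str
) -> list[dict]:
    """Dunn's post hoc vs a designated control, Bonferroni family adjustment.

    z statistics are built from pooled mean ranks with the standard tie
    correction; the family is the set of comparisons against the control.
    """
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    mean_ranks = {}
    i = 0
    for g in labels:
        n_g = groups[g].size
        mean_ranks[g] = float(np.mean(ranks[i : i + n_g]))
        i += n_g
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    others = [g for g in labels if g != control]
    rows = []
    for g in others:
        se = math.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_term)
            * (1.0 / groups[g].size + 1.0 / groups[control].size)
        )
        z = (mean_ranks[g] - mean_ranks[control]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {
                "group": g,
                "control": control,
                "z": float(z),
                "p_raw": float(p),
                "p_adjusted": min(1.0, float(p) * len(others)),
            }
        )
    return rows


def rank_tests(
    plate_values_by_group: Mapping[str, Sequence[float]],
    control: str | None = None,
) -> dict:
    """Nonparametric group comparison on plate means.

    Two groups: two-sided Mann-Whitney U.  More: Kruskal-Wallis followed by
    Dunn's pairwise comparisons against ``control`` (default: first group)
    with Bonferroni family adjustment.  Returns a plain dict report with
    statistics, p-values, and per-group n.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in plate_values_by_group.items()}
    if len(groups) < 2:
        raise ParameterError("rank_tests requires at least two groups")
    for name, vals in groups.items():
        if vals.size < 2:
            raise ParameterError(f"group {name!r} has fewer than 2 plates")
    ns = {k: int(v.size) for k, v in groups.items()}
    if len(groups) == 2:
        (la, va), (lb, vb) = groups.items()
        res = sps.mannwhitneyu(va, vb, alternative="two-sided")
        return {
            "test": "mann-whitney",
            "groups": list(groups),
            "n": ns,
            "U": float(res.statistic),
            "p": float(res.pvalue),
        }
    control = control if control is not None else next(iter(groups))
    if control not in groups:
        raise ParameterError(f"control group {control!r} not among the groups")
    kw = sps.kruskal(*groups.values())
    return {
        "test": "kruskal-wallis+dunn",
        "groups": list(groups),
        "n": ns,
        "H": float(kw.statistic),
        "p_kruskal": float(kw.pvalue),
        "pairwise": _dunns_test(groups, control),
    }


def events_for_tracks(
    tracks: Sequence[TrackRecord], min_event_frames: int = 1
) -> dict[str, list[BehaviorEvent]]:
    """Convenience: segment every track, keyed by track_id."""
    return {t.track_id: segment_events(t, min_event_frames) for t in tracks}
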