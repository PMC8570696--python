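"""Analysis constants and run configuration.

Every constant that parameterizes the standard foraging / optogenetics /
calcium analyses lives here, with the value used throughout the package as
its default.  Functions take these as keyword defaults so that a plain call
reproduces the standard analysis; the CLI reads overrides from a YAML config
and records the resolved values in a provenance JSON next to its outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Any

#: Local-search analysis window: 4-8 min after removal from food, seconds.
LOCAL_WINDOW_S: tuple[float, float] = (240.0, 480.0)
#: Global-search analysis window: 36-40 min after removal from food, seconds.
GLOBAL_WINDOW_S: tuple[float, float] = (2160.0, 2400.0)
#: Reversals shorter than this path length (body lengths) are classed SHORT.
SHORT_REVERSAL_MAX_BL: float = 0.5
#: Forward runs must last at least this long (s) to enter duration analyses.
MIN_FORWARD_RUN_S: float = 2.0
#: Minimum track length (s) for reversal / forward-run parameter analyses.
MIN_TRACK_S: float = 300.0

#: Pulse-aligned segment length (s); light occupies [50, 70) s of the segment.
PULSE_SEGMENT_S: float = 120.0
PULSE_ONSET_IN_SEGMENT_S: float = 50.0
PULSE_END_IN_SEGMENT_S: float = 70.0
#: Length (s) of the before/during windows used for the delta reversal frequency.
OPTO_DELTA_WINDOW_S: float = 18.0
#: Offsets (s, segment time) where the two 18 s windows begin.
OPTO_BEFORE_OFFSET_S: float = 32.0
OPTO_DURING_OFFSET_S: float = 50.0
#: Minimum duration (s) for a reversal to count as the first evoked reversal.
MIN_EVOKED_REVERSAL_S: float = 0.5

#: Boxcar smoothing window (s) applied to raw fluorescence.
CALCIUM_SMOOTH_S: float = 1.0
#: Boxcar smoothing window (s) applied to the dF/dt series.
DERIV_SMOOTH_S: float = 3.0
#: F0 = median of the samples at or below this quantile of smoothed F.
F0_LOWEST_FRACTION: float = 0.10
#: Traces whose peak dF/F0 does not exceed this never enter the ON state.
QUALIFY_DFF: float = 0.10
#: Initial binary assignment: ON wherever dF/F0 > this fraction of its max.
INITIAL_STATE_FMAX_FRACTION: float = 0.5
#: dF/dt transition thresholds as a fraction of the per-trace extrema.
DERIV_THRESHOLD_FACTOR: float = 0.25
#: Refined ON epochs shorter than this (s) are discarded as flicker.
MIN_ON_EPOCH_S: float = 1.0
#: Calcium analysis windows, seconds after conditioned-media removal.
CALCIUM_LOCAL_WINDOW_S: tuple[float, float] = (0.0, 300.0)
CALCIUM_GLOBAL_WINDOW_S: tuple[float, float] = (1800.0, 2100.0)

#: Significance level for distribution and rank tests.
ALPHA: float = 0.05
#: Minimum KS D statistic for a significant comparison to be discussable.
KS_EFFECT_CUTOFF: float = 0.15

SCHEMA_VERSION = "foragekit_track_v1"


@dataclasses.dataclass
class RunConfig:
    """Per-command parameter blocks for the CLI, loaded from YAML.

    Unset blocks fall back to the module constants above; the resolved
    values are always written to the provenance record, never guessed
    silently.
    """

    simulation: dict[str, Any] = dataclasses.field(default_factory=dict)
    analysis: dict[str, Any] = dataclasses.field(default_factory=dict)
    statistics: dict[str, Any] = dataclasses.field(default_factory=dict)
    seed: int = 0
    schema_version: str = SCHEMA_VERSION

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Stable SHA-256 hash of the canonical JSON form of the config."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def analysis_defaults() -> dict[str, Any]:
    """The resolved default constants, for provenance records and docs."""
    return {
        "local_window_s": list(LOCAL_WINDOW_S),
        "global_window_s": list(GLOBAL_WINDOW_S),
        "short_reversal_max_bl": SHORT_REVERSAL_MAX_BL,
        "min_forward_run_s": MIN_FORWARD_RUN_S,
        "min_track_s": MIN_TRACK_S,
        "pulse_segment_s": PULSE_SEGMENT_S,
        "pulse_onset_in_segment_s": PULSE_ONSET_IN_SEGMENT_S,
        "pulse_end_in_segment_s": PULSE_END_IN_SEGMENT_S,
        "opto_delta_window_s": OPTO_DELTA_WINDOW_S,
        "opto_before_offset_s": OPTO_BEFORE_OFFSET_S,
        "opto_during_offset_s": OPTO_DURING_OFFSET_S,
        "min_evoked_reversal_s": MIN_EVOKED_REVERSAL_S,
        "calcium_smooth_s": CALCIUM_SMOOTH_S,
        "deriv_smooth_s": DERIV_SMOOTH_S,
        "f0_lowest_fraction": F0_LOWEST_FRACTION,
        "qualify_dff": QUALIFY_DFF,
        "initial_state_fmax_fraction": INITIAL_STATE_FMAX_FRACTION,
        "deriv_threshold_factor": DERIV_THRESHOLD_FACTOR,
        "min_on_epoch_s": MIN_ON_EPOCH_S,
        "alpha": ALPHA,
        "ks_effect_cutoff": KS_EFFECT_CUTOFF,
        "schema_version": SCHEMA_VERSION,
    }
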