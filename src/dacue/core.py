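"""Domain types and time conventions for Pavlovian cue-value sessions.

All times are stored in seconds on a per-trial clock whose origin is the
trial start; analyses align on demand with :func:`align_times`.  Every
analysis window in the package is half-open ``[t0, t1)``.  Milliseconds
appear only in human-readable reports, never internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ValidationError",
    "EventTimes",
    "Trial",
    "TimingConfig",
    "StimulusSpec",
    "SaccadeRecord",
    "Session",
    "align_times",
    "michelson_from_weber",
    "VALUE_LABELS",
    "CONDITIONS",
    "CS_LOCATIONS",
    "EVENTS",
]

VALUE_LABELS = ("LR", "SR")
CONDITIONS = ("pre", "inactivation")
CS_LOCATIONS = ("upper", "lower")
EVENTS = ("FP", "CS", "RW")

#: tolerance for the Weber/Michelson consistency check on StimulusSpec
CONTRAST_TOL = 0.005


class ValidationError(ValueError):
    """Raised when a session, trial, or record violates a structural invariant."""


def michelson_from_weber(weber: float) -> float:
    """Convert a Weber contrast ``(L - Lb)/Lb`` to a Michelson contrast.

    With stimulus luminance ``L = Lb * (1 + W)`` against background ``Lb``,
    the Michelson contrast ``(L - Lb)/(L + Lb)`` reduces to ``W / (W + 2)``.

    Parameters
    ----------
    weber : float
        Weber contrast; must be > -1 (luminances are positive).
    """
    if weber <= -1.0:
        raise ValueError(f"Weber contrast must be > -1, got {weber}")
    return weber / (weber + 2.0)


@dataclass(frozen=True)
class EventTimes:
    """Absolute event timestamps (s) within one trial; trial start = 0."""

    fp_onset: float
    cs_onset: float
    cs_offset: float
    reward_time: float

    def validate(self, trial_id: Optional[int] = None) -> None:
        where = "" if trial_id is None else f" in trial {trial_id}"
        if not (self.fp_onset < self.cs_onset < self.cs_offset):
            raise ValidationError(
                f"event order must satisfy fp_onset < cs_onset < cs_offset{where}: "
                f"fp={self.fp_onset}, cs_on={self.cs_onset}, cs_off={self.cs_offset}"
            )
        if self.reward_time <= self.cs_onset:
            raise ValidationError(
                f"reward_time must follow cs_onset{where}: "
                f"rw={self.reward_time}, cs_on={self.cs_onset}"
            )
        if self.fp_onset < 0:
            raise ValidationError(f"fp_onset must be >= 0{where}")

    def time_of(self, event: str) -> float:
        """Timestamp of an alignment event: 'FP', 'CS' (onset) or 'RW'."""
        if event == "FP":
            return self.fp_onset
        if event == "CS":
            return self.cs_onset
        if event == "RW":
            return self.reward_time
        raise ValueError(f"unknown event {event!r}; expected one of {EVENTS}")


def _as_sorted_times(values: Sequence[float], what: str, trial_id: int) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{what} times must be 1-D in trial {trial_id}")
    if arr.size and np.any(np.diff(arr) < 0):
        raise ValidationError(f"{what} times not sorted ascending in trial {trial_id}")
    if arr.size and arr[0] < 0:
        raise ValidationError(f"{what} times must be >= 0 in trial {trial_id}")
    return arr


@dataclass
class Trial:
    """One Pavlovian trial: events, value label, condition, spikes and licks.

    ``spikes`` maps neuron id -> sorted spike times (s, trial clock); a trial
    may carry several simultaneously recorded neurons.
    """

    trial_id: int
    value_label: str
    condition: str
    cs_location: str
    events: EventTimes
    spikes: Dict[str, np.ndarray] = field(default_factory=dict)
    licks: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.licks = np.asarray(self.licks, dtype=float)
        self.spikes = {k: np.asarray(v, dtype=float) for k, v in self.spikes.items()}

    def validate(self) -> None:
        if self.value_label not in VALUE_LABELS:
            raise ValidationError(
                f"unknown value_label {self.value_label!r} in trial {self.trial_id}"
            )
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"unknown condition {self.condition!r} in trial {self.trial_id}"
            )
        if self.cs_location not in CS_LOCATIONS:
            raise ValidationError(
                f"unknown cs_location {self.cs_location!r} in trial {self.trial_id}"
            )
        self.events.validate(self.trial_id)
        self.licks = _as_sorted_times(self.licks, "lick", self.trial_id)
        for nid, st in self.spikes.items():
            self.spikes[nid] = _as_sorted_times(st, f"spike ({nid})", self.trial_id)


@dataclass(frozen=True)
class TimingConfig:
    """Task timing constants (s).

    The CS appears at a uniformly jittered delay after fixation-point onset
    and stays on for ``cs_duration`` (1.0 s for one animal, 1.7 s for the
    other — configurable, never hard-coded).  The large reward is delivered
    within the CS period; the small reward after CS offset.
    """

    fp_onset: float = 0.75
    cs_delay_min: float = 0.7
    cs_delay_max: float = 1.2
    cs_duration: float = 1.0
    lr_reward_delay: float = 0.9   # from CS onset, inside the CS period
    sr_reward_delay: float = 0.3   # from CS offset
    post_reward: float = 1.0       # recorded tail after reward delivery

    def trial_end(self, events: EventTimes) -> float:
        return events.reward_time + self.post_reward


@dataclass(frozen=True)
class StimulusSpec:
    """Conditioned-stimulus photometry/geometry.

    The two contrast measures must be mutually consistent:
    ``michelson == weber / (weber + 2)`` within ``CONTRAST_TOL``.
    """

    background_luminance: float = 1.0   # cd/m^2
    weber_contrast: float = 13.4
    michelson_contrast: float = 0.87
    size_deg: float = 2.2
    eccentricity_deg: float = 10.0
    direction_deg: float = 45.0

    def validate(self) -> None:
        if self.background_luminance <= 0:
            raise ValidationError("background luminance must be > 0")
        expected = michelson_from_weber(self.weber_contrast)
        if abs(self.michelson_contrast - expected) > CONTRAST_TOL:
            raise ValidationError(
                "inconsistent contrasts: Michelson "
                f"{self.michelson_contrast} vs Weber-implied {expected:.4f} "
                f"(tolerance {CONTRAST_TOL})"
            )


@dataclass(frozen=True)
class SaccadeRecord:
    """One visually guided saccade: target direction, block, latency (ms)."""

    target_direction: float
    condition: str
    latency_ms: float

    def validate(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r} in saccade record")
        if self.latency_ms <= 0:
            raise ValidationError(f"saccade latency must be > 0, got {self.latency_ms}")


@dataclass
class Session:
    """A recording session: a pre-injection control block followed by an
    inactivation block, with per-trial spikes and licks.

    ``block_start`` is the index of the first inactivation trial (the control
    block is about 60 trials in the task this models).
    """

    trials: List[Trial]
    neuron_ids: List[str]
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    timing: TimingConfig = field(default_factory=TimingConfig)
    block_start: int = 0
    #: generator parameters when synthetic (not serialized; ground-truth hook)
    provenance: Optional[object] = None

    def validate(self) -> None:
        self.stimulus.validate()
        if not 0 <= self.block_start <= len(self.trials):
            raise ValidationError(
                f"block_start {self.block_start} outside 0..{len(self.trials)}"
            )
        loc_map: Dict[str, str] = {}
        for i, trial in enumerate(self.trials):
            trial.validate()
            expected_cond = "pre" if i < self.block_start else "inactivation"
            if trial.condition != expected_cond:
                raise ValidationError(
                    f"trial {trial.trial_id}: condition {trial.condition!r} "
                    f"inconsistent with block boundary {self.block_start}"
                )
            prev = loc_map.setdefault(trial.value_label, trial.cs_location)
            if prev != trial.cs_location:
                raise ValidationError(
                    f"trial {trial.trial_id}: value_label->cs_location mapping "
                    f"changed within session ({trial.value_label}: {prev} -> "
                    f"{trial.cs_location})"
                )
            for nid in trial.spikes:
                if nid not in self.neuron_ids:
                    raise ValidationError(
                        f"trial {trial.trial_id}: unknown neuron id {nid!r}"
                    )

    def select(self, value_label: Optional[str] = None,
               condition: Optional[str] = None) -> List[Trial]:
        """Trials filtered by value label and/or condition, in block order."""
        out = []
        for t in self.trials:
            if value_label is not None and t.value_label != value_label:
                continue
            if condition is not None and t.condition != condition:
                continue
            out.append(t)
        return out

    def aligned_spikes(self, neuron_id: str, event: str,
                       window: Tuple[float, float],
                       value_label: Optional[str] = None,
                       condition: Optional[str] = None) -> List[np.ndarray]:
        """Per-trial event-relative spike times inside ``window`` (half-open)."""
        return [
            align_times(t.spikes.get(neuron_id, np.empty(0)),
                        t.events.time_of(event), window)
            for t in self.select(value_label, condition)
        ]


def align_times(times: Sequence[float], event: float,
                window: Tuple[float, float]) -> np.ndarray:
    """Shift ``times`` to be relative to ``event`` and clip to half-open ``window``.

    Returns ``t - event`` for every ``t`` with ``t0 <= t - event < t1``,
    sorted ascending.
    """
    t0, t1 = window
    if t0 >= t1:
        raise ValueError(f"empty or inverted window [{t0}, {t1})")
    rel = np.asarray(times, dtype=float) - float(event)
    return rel[(rel >= t0) & (rel < t1)]
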