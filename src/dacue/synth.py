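"""Synthetic Pavlovian sessions with known ground truth.

The generator emulates the statistical structure the analyses assume: a
fixation point, a value-labelled conditioned stimulus at a jittered delay,
reward delivery, inhomogeneous-Poisson spike trains with event-locked
Gaussian intensity bumps (value-coded at the CS), anticipatory licking
confined to the cue-reward interval, and visually guided saccade latencies
with an inactivation-induced shift in one target direction only.

Spike trains are drawn by thinning against the peak intensity, which is
exact for an inhomogeneous Poisson process.  A single master seed spawns
independent per-trial, per-component substreams, so adding trials to a
session never perturbs earlier trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    EventTimes,
    SaccadeRecord,
    Session,
    StimulusSpec,
    TimingConfig,
    Trial,
    michelson_from_weber,  # noqa: F401  (re-exported: contrast op lives with the generator's stimulus spec)
)

__all__ = [
    "ResponseKernel",
    "LickModel",
    "SaccadeModel",
    "SynthParams",
    "default_kernels",
    "generate_session",
    "generate_spike_train",
    "generate_licks",
    "generate_saccades",
    "intensity",
    "michelson_from_weber",
]

# substream component codes (keep stable: they define the random layout)
_COMP_TIMING = 0
_COMP_LICKS = 2
_COMP_SPIKES_BASE = 1000
_COMP_SACCADES = 3


@dataclass(frozen=True)
class ResponseKernel:
    """Event-locked Gaussian intensity bump.

    ``onset_latency`` is the ground-truth response *onset* (s after the
    event); the Gaussian is centred at ``onset_latency + 2*width_sigma`` so
    that the bump rises from near zero exactly at the bookkept onset.
    Amplitudes are peak rates (spikes/s) added to baseline, separately for
    large-reward (LR) and small-reward (SR) trials; during the inactivation
    block both are multiplied by ``condition_scale_inactivation``.
    """

    event: str                      # 'FP', 'CS' or 'RW'
    onset_latency: float            # s
    width_sigma: float              # s
    amplitude_lr: float             # spikes/s
    amplitude_sr: float             # spikes/s
    condition_scale_inactivation: float = 1.0

    def amplitude(self, value_label: str, condition: str) -> float:
        amp = self.amplitude_lr if value_label == "LR" else self.amplitude_sr
        if condition == "inactivation":
            amp *= self.condition_scale_inactivation
        return amp

    def validate(self) -> None:
        if self.width_sigma <= 0:
            raise ValueError(f"kernel width_sigma must be > 0, got {self.width_sigma}")


@dataclass(frozen=True)
class LickModel:
    """Poisson licking: baseline everywhere, elevated in the anticipatory
    window ([CS onset, reward) on LR trials; [CS offset, reward) on SR)."""

    baseline_rate: float = 0.5        # licks/s
    anticipatory_rate: float = 3.0    # licks/s
    anticipatory_scale_inactivation: float = 1.0

    def validate(self) -> None:
        if self.baseline_rate < 0 or self.anticipatory_rate < 0:
            raise ValueError("lick rates must be >= 0")
        if self.anticipatory_scale_inactivation < 0:
            raise ValueError("anticipatory_scale_inactivation must be >= 0")


@dataclass(frozen=True)
class SaccadeModel:
    """Gaussian saccade latencies (truncated at a physiological floor), with
    a latency shift added only to the muscimol-affected target direction
    during the inactivation block."""

    directions: Tuple[float, ...] = (45.0, 135.0, -135.0, -45.0)
    latency_mean_ms: float = 180.0
    latency_sd_ms: float = 20.0
    affected_direction: float = 45.0
    inactivation_shift_ms: float = 53.0
    min_latency_ms: float = 50.0

    def validate(self) -> None:
        if self.latency_sd_ms <= 0:
            raise ValueError("latency SD must be > 0")
        if self.min_latency_ms <= 0:
            raise ValueError("latency floor must be > 0")


def default_kernels() -> Tuple[ResponseKernel, ...]:
    """Kernels emulating the study's response pattern: phasic FP response
    equal across values, value-coded CS response (strong LR, weak SR), and
    no response to the fully predicted reward."""
    return (
        ResponseKernel("FP", onset_latency=0.085, width_sigma=0.015,
                       amplitude_lr=20.0, amplitude_sr=20.0),
        ResponseKernel("CS", onset_latency=0.085, width_sigma=0.015,
                       amplitude_lr=25.0, amplitude_sr=7.5),
        ResponseKernel("RW", onset_latency=0.100, width_sigma=0.015,
                       amplitude_lr=0.0, amplitude_sr=0.0),
    )


@dataclass(frozen=True)
class SynthParams:
    """Full generative specification of a synthetic session."""

    n_trials_pre: int = 60
    n_trials_inact: int = 60
    baseline_rate: float = 5.0          # spikes/s; screening range is 1-10 Hz
    kernels: Tuple[ResponseKernel, ...] = field(default_factory=default_kernels)
    lick_model: LickModel = field(default_factory=LickModel)
    saccade_model: SaccadeModel = field(default_factory=SaccadeModel)
    timing: TimingConfig = field(default_factory=TimingConfig)
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    neuron_ids: Tuple[str, ...] = ("n1",)

    def validate(self) -> None:
        if self.n_trials_pre <= 0 or self.n_trials_inact < 0:
            raise ValueError("trial counts must be positive (inactivation may be 0)")
        if self.baseline_rate < 0:
            raise ValueError("baseline rate must be >= 0")
        for k in self.kernels:
            k.validate()
        self.lick_model.validate()
        self.saccade_model.validate()
        self.stimulus.validate()
        # conservative feasibility bound: baseline plus all negative peak
        # amplitudes must stay >= 0 for every (value, condition) cell
        for vl in ("LR", "SR"):
            for cond in ("pre", "inactivation"):
                lower = self.baseline_rate + sum(
                    min(k.amplitude(vl, cond), 0.0) for k in self.kernels)
                if lower < 0:
                    raise ValueError(
                        f"intensity could go negative for {vl}/{cond} "
                        f"(lower bound {lower:.3f} spikes/s)")

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(master_seed),) + key))


def intensity(t: np.ndarray, events: EventTimes, value_label: str,
              condition: str, baseline: float,
              kernels: Sequence[ResponseKernel]) -> np.ndarray:
    """Spike intensity lambda(t) (spikes/s) on the trial clock."""
    t = np.asarray(t, dtype=float)
    lam = np.full_like(t, float(baseline))
    for k in kernels:
        amp = k.amplitude(value_label, condition)
        if amp == 0.0:
            continue
        center = events.time_of(k.event) + k.onset_latency + 2.0 * k.width_sigma
        lam += amp * np.exp(-0.5 * ((t - center) / k.width_sigma) ** 2)
    return lam


def generate_spike_train(events: EventTimes, value_label: str, condition: str,
                         baseline: float, kernels: Sequence[ResponseKernel],
                         t_end: float, rng: np.random.Generator) -> np.ndarray:
    """One trial's spike times on [0, t_end) by thinning against lambda_max."""
    lam_max = baseline + sum(max(k.amplitude(value_label, condition), 0.0)
                             for k in kernels)
    if lam_max <= 0:
        raise ValueError("lambda_max <= 0: no positive intensity to simulate")
    n = rng.poisson(lam_max * t_end)
    cand = np.sort(rng.uniform(0.0, t_end, size=n))
    u = rng.uniform(0.0, 1.0, size=n)
    lam = intensity(cand, events, value_label, condition, baseline, kernels)
    return cand[u * lam_max < lam]


def _poisson_times(rate: float, t0: float, t1: float,
                   rng: np.random.Generator) -> np.ndarray:
    if rate <= 0 or t1 <= t0:
        # draw nothing, but consume no stream state asymmetrically
        rng.poisson(0.0)
        return np.empty(0)
    n = rng.poisson(rate * (t1 - t0))
    return rng.uniform(t0, t1, size=n)


def generate_licks(events: EventTimes, value_label: str, condition: str,
                   lick_model: LickModel, t_end: float,
                   rng: np.random.Generator) -> np.ndarray:
    """One trial's lick times: baseline Poisson everywhere, anticipatory
    rate inside the value-dependent cue-reward window."""
    lick_model.validate()
    if value_label == "LR":
        w0, w1 = events.cs_onset, events.reward_time
    else:
        w0, w1 = events.cs_offset, events.reward_time
    w1 = min(w1, t_end)
    ant = lick_model.anticipatory_rate
    if condition == "inactivation":
        ant *= lick_model.anticipatory_scale_inactivation
    base = lick_model.baseline_rate
    parts = [
        _poisson_times(base, 0.0, w0, rng),
        _poisson_times(ant, w0, w1, rng),
        _poisson_times(base, w1, t_end, rng),
    ]
    return np.sort(np.concatenate(parts))


def generate_session(params: SynthParams, seed: int) -> Session:
    """Generate a full two-block session; reproducible given (params, seed).

    LR/SR labels are assigned with equal probability per trial; the CS onset
    delay after fixation-point onset is Uniform[0.7, 1.2] s (configurable via
    the timing constants).  The generated session carries ``params`` in its
    ``provenance`` field so downstream tests can compare estimates against
    ground truth.
    """
    params.validate()
    tm = params.timing
    n_total = params.n_trials_pre + params.n_trials_inact
    trials: List[Trial] = []
    for i in range(n_total):
        condition = "pre" if i < params.n_trials_pre else "inactivation"
        rng_t = _rng(seed, i, _COMP_TIMING)
        value_label = "LR" if rng_t.random() < 0.5 else "SR"
        cs_location = "upper" if value_label == "LR" else "lower"
        delay = rng_t.uniform(tm.cs_delay_min, tm.cs_delay_max)
        cs_onset = tm.fp_onset + delay
        cs_offset = cs_onset + tm.cs_duration
        if value_label == "LR":
            reward = cs_onset + tm.lr_reward_delay
        else:
            reward = cs_offset + tm.sr_reward_delay
        events = EventTimes(fp_onset=tm.fp_onset, cs_onset=cs_onset,
                            cs_offset=cs_offset, reward_time=reward)
        t_end = tm.trial_end(events)
        spikes = {}
        for j, nid in enumerate(params.neuron_ids):
            rng_s = _rng(seed, i, _COMP_SPIKES_BASE + j)
            spikes[nid] = generate_spike_train(
                events, value_label, condition, params.baseline_rate,
                params.kernels, t_end, rng_s)
        rng_l = _rng(seed, i, _COMP_LICKS)
        licks = generate_licks(events, value_label, condition,
                               params.lick_model, t_end, rng_l)
        trials.append(Trial(trial_id=i, value_label=value_label,
                            condition=condition, cs_location=cs_location,
                            events=events, spikes=spikes, licks=licks))
    session = Session(trials=trials, neuron_ids=list(params.neuron_ids),
                      stimulus=params.stimulus, timing=tm,
                      block_start=params.n_trials_pre)
    session.provenance = params
    session.validate()
    return session


def generate_saccades(model: SaccadeModel, n_per_cell: int,
                      seed: int) -> List[SaccadeRecord]:
    """Saccade latencies for every condition x target direction cell.

    Latencies are Gaussian, resampled until above the floor (default 50 ms);
    the inactivation shift applies only to the affected direction.
    """
    model.validate()
    rng = _rng(seed, _COMP_SACCADES)
    records: List[SaccadeRecord] = []
    for condition in ("pre", "inactivation"):
        for direction in model.directions:
            mean = model.latency_mean_ms
            if condition == "inactivation" and direction == model.affected_direction:
                mean += model.inactivation_shift_ms
            lat = rng.normal(mean, model.latency_sd_ms, size=n_per_cell)
            while np.any(lat <= model.min_latency_ms):
                bad = lat <= model.min_latency_ms
                lat[bad] = rng.normal(mean, model.latency_sd_ms, size=bad.sum())
            records.extend(
                SaccadeRecord(target_direction=direction, condition=condition,
                              latency_ms=float(v))
                for v in lat)
    return records
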