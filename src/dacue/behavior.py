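"""Conditioned-licking and saccade-latency analyses.

Anticipatory licking in the interval between cue onset and reward delivery
is the conditioned response: its rate should discriminate large-reward from
small-reward cues if the animal has learned the cue values, and that
discrimination should survive collicular inactivation if cortical visual
processing suffices to drive it.  Saccade-latency prolongation in the
affected visual field is the positive control that the inactivation worked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union
import warnings

import numpy as np

from .core import SaccadeRecord, Session, Trial, align_times
from .stats import (
    PermutationResult,
    TestResult,
    paired_permutation_test,
    permutation_test,
    two_sample_t,
    wilcoxon_signed_rank,
)

__all__ = [
    "LickingRateResult",
    "CRSummary",
    "SaccadeProlongation",
    "licking_rate",
    "session_mean_rates",
    "paired_rate_differences",
    "cr_discrimination",
    "inactivation_effect_licking",
    "experiment_inactivation_effect",
    "saccade_prolongation",
]

LICK_BIN = 0.1  # s; counting bin for licking-rate time courses

#: the fixed-window variant of the licking measure (s after CS onset)
FIXED_LICK_WINDOW = (0.7, 1.3)


@dataclass(frozen=True)
class LickingRateResult:
    trial_id: int
    rate: float                       # licks/s
    window: Tuple[float, float]       # s, absolute trial clock
    n_licks: int
    bin_counts: np.ndarray = field(default_factory=lambda: np.empty(0))
    bin_edges: np.ndarray = field(default_factory=lambda: np.empty(0))


def _lick_window(trial: Trial, rule: Union[str, Tuple[float, float]]):
    ev = trial.events
    if rule == "cs_to_reward":
        return ev.cs_onset, ev.reward_time
    if rule == "fixed":
        return ev.cs_onset + FIXED_LICK_WINDOW[0], ev.cs_onset + FIXED_LICK_WINDOW[1]
    if isinstance(rule, tuple) and len(rule) == 2:
        return ev.cs_onset + rule[0], ev.cs_onset + rule[1]
    raise ValueError(f"unknown licking window rule {rule!r}")


def licking_rate(trial: Trial, window_rule: Union[str, Tuple[float, float]] = "cs_to_reward",
                 bin_s: float = LICK_BIN) -> LickingRateResult:
    """Licks per second in the half-open analysis window of one trial.

    ``window_rule`` is ``'cs_to_reward'`` (cue onset to reward delivery,
    the default), ``'fixed'`` (0.7-1.3 s after cue onset), or an explicit
    ``(t0, t1)`` offset pair after cue onset.  Binned counts (``bin_s``
    wide) are returned for time-course summaries.
    """
    t0, t1 = _lick_window(trial, window_rule)
    if t1 <= t0:
        raise ValueError(f"empty licking window [{t0}, {t1}) in trial {trial.trial_id}")
    in_win = align_times(trial.licks, t0, (0.0, t1 - t0))
    n_bins = int(np.ceil((t1 - t0) / bin_s))
    edges = t0 + bin_s * np.arange(n_bins + 1)
    counts, _ = np.histogram(trial.licks, bins=edges)
    return LickingRateResult(trial_id=trial.trial_id,
                             rate=in_win.size / (t1 - t0),
                             window=(t0, t1), n_licks=int(in_win.size),
                             bin_counts=counts, bin_edges=edges)


def session_mean_rates(session: Session, condition: Optional[str] = None,
                       window_rule: Union[str, Tuple[float, float]] = "cs_to_reward",
                       ) -> Tuple[float, float]:
    """(mean LR rate, mean SR rate) over the session's trials (licks/s)."""
    lr = [licking_rate(t, window_rule).rate
          for t in session.select("LR", condition)]
    sr = [licking_rate(t, window_rule).rate
          for t in session.select("SR", condition)]
    if not lr or not sr:
        raise ValueError("session lacks LR or SR trials for the requested condition")
    return float(np.mean(lr)), float(np.mean(sr))


def paired_rate_differences(session: Session, condition: Optional[str] = None,
                            window_rule: Union[str, Tuple[float, float]] = "cs_to_reward",
                            ) -> np.ndarray:
    """Per-pair LR - SR licking-rate differences within a block.

    The i-th LR trial is paired with the i-th SR trial in block order;
    surplus trials of the longer list are dropped.
    """
    lr = [licking_rate(t, window_rule).rate for t in session.select("LR", condition)]
    sr = [licking_rate(t, window_rule).rate for t in session.select("SR", condition)]
    n = min(len(lr), len(sr))
    return np.asarray(lr[:n]) - np.asarray(sr[:n])


@dataclass(frozen=True)
class CRSummary:
    """Conditioned-response discrimination summary."""

    mean_rate_lr: float
    mean_rate_sr: float
    differences: np.ndarray
    test: TestResult


def cr_discrimination(rate_pairs: Sequence[Tuple[float, float]]) -> CRSummary:
    """Paired Wilcoxon on per-unit (LR, SR) licking rates.

    Units are typically sessions (one mean-rate pair per session, matching
    an N-of-sessions design) but may be trial pairs.
    """
    pairs = np.asarray(rate_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] == 0:
        raise ValueError("rate_pairs must be a nonempty sequence of (LR, SR) pairs")
    diffs = pairs[:, 0] - pairs[:, 1]
    return CRSummary(mean_rate_lr=float(pairs[:, 0].mean()),
                     mean_rate_sr=float(pairs[:, 1].mean()),
                     differences=diffs,
                     test=wilcoxon_signed_rank(diffs))


def inactivation_effect_licking(session: Session,
                                window_rule: Union[str, Tuple[float, float]] = "cs_to_reward",
                                n_perm: int = 10_000,
                                seed: Optional[int] = None) -> Dict[str, object]:
    """Within-session test of whether cue-value discrimination changed
    between the control and inactivation blocks.

    The per-pair LR - SR rate differences of each block are compared by a
    Wilcoxon signed-rank on order-paired block differences and by a
    two-sample label-shuffling permutation test on the same per-pair
    differences; both results are reported.
    """
    pre = paired_rate_differences(session, "pre", window_rule)
    post = paired_rate_differences(session, "inactivation", window_rule)
    if pre.size < 2 or post.size < 2:
        raise ValueError("each block needs at least 2 LR/SR trial pairs")
    n = min(pre.size, post.size)
    block_diffs = post[:n] - pre[:n]
    try:
        wtest: Optional[TestResult] = wilcoxon_signed_rank(block_diffs)
    except ValueError:   # all paired block differences zero (identical blocks)
        wtest = None
    perm = permutation_test(post, pre, n_perm=n_perm, seed=seed)
    return {"wilcoxon": wtest, "permutation": perm,
            "mean_diff_pre": float(pre.mean()),
            "mean_diff_inactivation": float(post.mean())}


def experiment_inactivation_effect(sessions: Sequence[Session],
                                   window_rule: Union[str, Tuple[float, float]] = "cs_to_reward",
                                   n_perm: int = 10_000,
                                   seed: Optional[int] = None) -> Dict[str, object]:
    """Session-level (N = number of sessions) pre-vs-inactivation comparison
    of the LR - SR licking-rate difference, the design behind an N = 9
    paired Wilcoxon; a sign-flipping permutation test accompanies it.
    """
    if len(sessions) < 2:
        raise ValueError("need >= 2 sessions for the session-level comparison")
    pre_d, post_d = [], []
    for s in sessions:
        lr_pre, sr_pre = session_mean_rates(s, "pre", window_rule)
        lr_post, sr_post = session_mean_rates(s, "inactivation", window_rule)
        pre_d.append(lr_pre - sr_pre)
        post_d.append(lr_post - sr_post)
    diffs = np.asarray(post_d) - np.asarray(pre_d)
    try:
        wtest: Optional[TestResult] = wilcoxon_signed_rank(diffs)
    except ValueError:
        wtest = None
    perm = paired_permutation_test(diffs, n_perm=n_perm, seed=seed)
    return {"wilcoxon": wtest, "permutation": perm,
            "session_diffs_pre": np.asarray(pre_d),
            "session_diffs_inactivation": np.asarray(post_d)}


@dataclass(frozen=True)
class SaccadeProlongation:
    direction: float
    delta_latency_ms: float       # inactivation mean - pre mean
    test: TestResult
    n_pre: int
    n_inactivation: int


def saccade_prolongation(records: Sequence[SaccadeRecord],
                         ) -> List[SaccadeProlongation]:
    """Per-direction latency change between blocks, with a Welch t-test.

    Directions with fewer than 2 records in either condition are skipped
    with a warning.  Directions are matched exactly (targets are discrete).
    """
    by_dir: Dict[float, Dict[str, List[float]]] = {}
    for r in records:
        by_dir.setdefault(r.target_direction, {"pre": [], "inactivation": []})
        by_dir[r.target_direction][r.condition].append(r.latency_ms)
    out: List[SaccadeProlongation] = []
    for direction in sorted(by_dir):
        pre = by_dir[direction]["pre"]
        post = by_dir[direction]["inactivation"]
        if len(pre) < 2 or len(post) < 2:
            warnings.warn(
                f"direction {direction}: fewer than 2 records per condition; skipped")
            continue
        delta = float(np.mean(post) - np.mean(pre))
        out.append(SaccadeProlongation(direction=direction,
                                       delta_latency_ms=delta,
                                       test=two_sample_t(pre, post),
                                       n_pre=len(pre), n_inactivation=len(post)))
    return out
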