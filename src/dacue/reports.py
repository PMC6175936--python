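"""Pipeline orchestration and report rendering.

``run_full_pipeline`` runs every analysis stage on a session — conditioned
licking discrimination, the pre-vs-inactivation licking comparison, saccade
prolongation (when saccade records are supplied), per-neuron and population
response-magnitude comparisons, and the two latency detectors per block —
and collects the results with full provenance (config snapshot, seeds,
package version).  Stage failures are recorded and remaining stages still
run.  Reports render to JSON or markdown.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import __version__ as _pkg_version
from .behavior import (
    inactivation_effect_licking,
    saccade_prolongation,
    session_mean_rates,
)
from .core import SaccadeRecord, Session
from .da import (
    BASELINE_WINDOW,
    RESPONSE_WINDOWS,
    V_EVAL_STEP,
    V_SIGMA,
    baseline_stats,
    l_latency,
    population_pre_post,
    pre_post_comparison,
    spike_density,
    v_latency,
    window_rate,
)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "Report", "run_full_pipeline", "render_report"]

ANALYSIS_SPAN = (-0.5, 1.0)


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable analysis settings; defaults are the study-derived values
    (response windows 0.100-0.300 s after FP/CS and 0.150-0.350 s after
    reward, baseline -0.5-0 s, alpha 0.05, persistence 0.015 s)."""

    kernel_sigma: float = 0.010          # s, SDF smoothing
    v_sigma: float = V_SIGMA             # s, single-trial smoothing for V
    v_eval_step: float = V_EVAL_STEP     # s, sign-test evaluation spacing
    persistence: float = 0.015           # s, sustained-significance requirement
    alpha: float = 0.05
    baseline_window: Tuple[float, float] = BASELINE_WINDOW
    response_windows: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(RESPONSE_WINDOWS))
    licking_window_rule: str = "cs_to_reward"
    pairing: str = "order"
    n_perm: int = 10_000
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["baseline_window"] = list(self.baseline_window)
        d["response_windows"] = {k: list(v) for k, v in self.response_windows.items()}
        return d


@dataclass
class Report:
    """Structured per-stage results plus provenance."""

    config: AnalysisConfig
    stages: Dict[str, object] = field(default_factory=dict)
    errors: Dict[str, str] = field(default_factory=dict)
    provenance: Dict[str, object] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"config": self.config.to_dict(),
                "stages": _jsonable(self.stages),
                "errors": dict(self.errors),
                "provenance": _jsonable(self.provenance)}


def _jsonable(obj):
    if obj is None or isinstance(obj, (bool, int, str)):
        return obj
    if isinstance(obj, float):
        return float(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(x) for x in obj.tolist()]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    if dataclasses.is_dataclass(obj):
        return _jsonable(dataclasses.asdict(obj))
    return repr(obj)


def _stage(report: Report, name: str):
    """Decorator-free stage runner: record result or error, keep going."""
    def run(fn, *args, **kwargs):
        try:
            report.stages[name] = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            logger.warning("stage %s failed: %s", name, exc)
            report.errors[name] = f"{type(exc).__name__}: {exc}"
    return run


def run_full_pipeline(session: Session,
                      saccades: Optional[Sequence[SaccadeRecord]] = None,
                      config: Optional[AnalysisConfig] = None) -> Report:
    """Run behavior, saccade, response-magnitude and latency stages."""
    cfg = config or AnalysisConfig()
    report = Report(config=cfg)
    report.provenance = {
        "package_version": _pkg_version,
        "n_trials": len(session.trials),
        "block_start": session.block_start,
        "neuron_ids": list(session.neuron_ids),
        "seed": cfg.seed,
    }
    logger.info("pipeline start: %d trials, %d neurons",
                len(session.trials), len(session.neuron_ids))

    def licking_stage():
        # within one session, discrimination is tested on order-paired
        # LR/SR trial rates of the control block
        from .behavior import paired_rate_differences
        from .stats import wilcoxon_signed_rank
        out = {}
        for cond in ("pre", "inactivation"):
            try:
                lr, sr = session_mean_rates(session, cond, cfg.licking_window_rule)
            except ValueError:
                continue
            out[cond] = {"mean_rate_lr": lr, "mean_rate_sr": sr}
        diffs = paired_rate_differences(session, "pre", cfg.licking_window_rule)
        out["pre_trialpair_wilcoxon"] = wilcoxon_signed_rank(diffs)
        return out

    _stage(report, "licking")(licking_stage)
    _stage(report, "licking_inactivation_effect")(
        inactivation_effect_licking, session,
        cfg.licking_window_rule, cfg.n_perm, cfg.seed)
    if saccades is not None:
        _stage(report, "saccades")(saccade_prolongation, list(saccades))

    def magnitudes_stage():
        out = {}
        pop_pre, pop_post = [], []
        for nid in session.neuron_ids:
            per_event = {}
            for event, window in cfg.response_windows.items():
                lab = "LR"  # magnitude comparisons follow the large-reward trials
                pre = session.aligned_spikes(nid, event, window, lab, "pre")
                post = session.aligned_spikes(nid, event, window, lab, "inactivation")
                if len(pre) < 2 or len(post) < 2:
                    continue
                wr_pre = window_rate(pre, event, window)
                wr_post = window_rate(post, event, window)
                comp = pre_post_comparison(wr_pre.rates, wr_post.rates,
                                           n_perm=cfg.n_perm, seed=cfg.seed)
                per_event[event] = {
                    "pre_mean": wr_pre.mean, "pre_sd": wr_pre.sd,
                    "post_mean": wr_post.mean, "post_sd": wr_post.sd,
                    "comparison": comp,
                }
                if event == "CS":
                    pop_pre.append(wr_pre.mean)
                    pop_post.append(wr_post.mean)
            out[nid] = per_event
        if len(pop_pre) >= 5:
            out["population_cs_wilcoxon"] = population_pre_post(pop_pre, pop_post)
        return out

    _stage(report, "response_magnitudes")(magnitudes_stage)

    def latency_stage():
        out = {}
        for cond in ("pre", "inactivation"):
            per_cond = {}
            for nid in session.neuron_ids:
                lr = session.aligned_spikes(nid, "CS", ANALYSIS_SPAN, "LR", cond)
                sr = session.aligned_spikes(nid, "CS", ANALYSIS_SPAN, "SR", cond)
                if not lr:
                    continue
                sdf = spike_density(lr, sigma=cfg.kernel_sigma, span=ANALYSIS_SPAN)
                base = baseline_stats(sdf, cfg.baseline_window)
                lat = v_latency(lr, sr, sigma=cfg.v_sigma, span=ANALYSIS_SPAN,
                                eval_step=cfg.v_eval_step, alpha=cfg.alpha,
                                persistence=cfg.persistence, pairing=cfg.pairing,
                                pairing_seed=cfg.seed)
                lat.l = l_latency(sdf, base)
                lat.threshold = base.mean + 2.0 * base.sd
                per_cond[nid] = lat
            out[cond] = per_cond
        return out

    _stage(report, "latencies")(latency_stage)
    return report


def _fmt_latency(value: Optional[float]) -> str:
    return "none" if value is None else f"{value * 1000:.0f} ms"


def render_report(report: Report, fmt: str = "json") -> str:
    """Render a report as a JSON document or markdown summary tables."""
    if fmt == "json":
        return json.dumps(report.to_dict(), indent=1, sort_keys=True)
    if fmt != "markdown":
        raise ValueError(f"unknown report format {fmt!r}")

    lines: List[str] = ["# Session analysis report", ""]
    lines.append(f"package version: {report.provenance.get('package_version', '?')}")
    lines.append("")
    mags = report.stages.get("response_magnitudes") or {}
    neuron_rows = [(nid, ev) for nid, ev in mags.items()
                   if isinstance(ev, dict) and nid != "population_cs_wilcoxon"]
    if neuron_rows:
        lines += ["## Response magnitudes (pre vs inactivation)", "",
                  "| neuron | event | pre mean±SD (sp/s) | inact mean±SD (sp/s) | t p | perm p |",
                  "|---|---|---|---|---|---|"]
        for nid, per_event in neuron_rows:
            for event, row in per_event.items():
                comp = row["comparison"]
                t = comp.get("t_test")
                t_p = f"{t.p_two_sided:.4f}" if t is not None else "n/a"
                perm = comp["permutation"]
                lines.append(
                    f"| {nid} | {event} | {row['pre_mean']:.2f}±{row['pre_sd']:.2f} "
                    f"| {row['post_mean']:.2f}±{row['post_sd']:.2f} "
                    f"| {t_p} | {perm.p_two_sided:.4f} |")
        lines.append("")
    lats = report.stages.get("latencies") or {}
    if lats:
        lines += ["## Response latencies", "",
                  "| condition | neuron | L | V | significant spans |",
                  "|---|---|---|---|---|"]
        for cond, per_cond in lats.items():
            for nid, lat in per_cond.items():
                spans = "; ".join(f"{a*1000:.0f}-{b*1000:.0f} ms"
                                  for a, b in lat.significant_spans) or "none"
                lines.append(f"| {cond} | {nid} | {_fmt_latency(lat.l)} "
                             f"| {_fmt_latency(lat.v)} | {spans} |")
        lines.append("")
    if report.errors:
        lines += ["## Stage errors", ""]
        lines += [f"- {k}: {v}" for k, v in report.errors.items()]
        lines.append("")
    return "\n".join(lines)
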