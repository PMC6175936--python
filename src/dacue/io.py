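"""Plain-text session I/O.

A session directory holds four CSV files plus one JSON sidecar:

* ``trials.csv`` — trial_id, value_label, condition, cs_location, fp_onset,
  cs_onset, cs_offset, reward_time (times in s, '.' decimal)
* ``spikes.csv`` — trial_id, neuron_id, spike_time
* ``licks.csv`` — trial_id, lick_time
* ``saccades.csv`` — condition, target_direction, latency_ms (optional file)
* ``session.json`` — stimulus spec, timing constants, block boundary, neuron ids

Writing is deterministic: rows sorted, floats rendered with their shortest
exact representation, so identical sessions produce byte-identical files
and values round-trip exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd

from .core import (
    EventTimes,
    SaccadeRecord,
    Session,
    StimulusSpec,
    TimingConfig,
    Trial,
    ValidationError,
)

__all__ = ["read_session", "write_session", "read_saccades", "write_saccades"]

_TRIAL_COLS = ["trial_id", "value_label", "condition", "cs_location",
               "fp_onset", "cs_onset", "cs_offset", "reward_time"]
_SPIKE_COLS = ["trial_id", "neuron_id", "spike_time"]
_LICK_COLS = ["trial_id", "lick_time"]
_SACCADE_COLS = ["condition", "target_direction", "latency_ms"]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    # default float rendering is shortest-repr: exact round-trip and
    # deterministic, hence byte-stable output for identical sessions
    df.to_csv(path, index=False, lineterminator="\n")


def write_session(session: Session, path: Union[str, os.PathLike]) -> None:
    """Write a validated session to ``path`` (a directory, created if absent)."""
    session.validate()
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)

    trial_rows, spike_rows, lick_rows = [], [], []
    for t in session.trials:
        ev = t.events
        trial_rows.append((t.trial_id, t.value_label, t.condition, t.cs_location,
                           ev.fp_onset, ev.cs_onset, ev.cs_offset, ev.reward_time))
        for nid in sorted(t.spikes):
            for s in t.spikes[nid]:
                spike_rows.append((t.trial_id, nid, s))
        for lk in t.licks:
            lick_rows.append((t.trial_id, lk))

    _write_csv(pd.DataFrame(trial_rows, columns=_TRIAL_COLS), out / "trials.csv")
    _write_csv(pd.DataFrame(spike_rows, columns=_SPIKE_COLS), out / "spikes.csv")
    _write_csv(pd.DataFrame(lick_rows, columns=_LICK_COLS), out / "licks.csv")

    meta = {
        "stimulus": asdict(session.stimulus),
        "timing": asdict(session.timing),
        "block_start": session.block_start,
        "neuron_ids": list(session.neuron_ids),
    }
    with open(out / "session.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_session(path: Union[str, os.PathLike]) -> Session:
    """Read and validate a session directory written by :func:`write_session`."""
    src = Path(path)
    try:
        trials_df = pd.read_csv(src / "trials.csv", float_precision="round_trip")
        spikes_df = pd.read_csv(src / "spikes.csv", float_precision="round_trip")
        licks_df = pd.read_csv(src / "licks.csv", float_precision="round_trip")
        with open(src / "session.json", encoding="utf-8") as fh:
            meta = json.load(fh)
    except FileNotFoundError as exc:
        raise ValidationError(f"missing session file: {exc.filename}") from exc

    for df, cols, name in ((trials_df, _TRIAL_COLS, "trials.csv"),
                           (spikes_df, _SPIKE_COLS, "spikes.csv"),
                           (licks_df, _LICK_COLS, "licks.csv")):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValidationError(f"{name}: missing column(s) {missing}")

    spikes_by_trial = {tid: g for tid, g in spikes_df.groupby("trial_id")}
    licks_by_trial = {tid: g for tid, g in licks_df.groupby("trial_id")}

    trials: List[Trial] = []
    for row in trials_df.itertuples(index=False):
        tid = int(row.trial_id)
        ev = EventTimes(float(row.fp_onset), float(row.cs_onset),
                        float(row.cs_offset), float(row.reward_time))
        spikes = {}
        if tid in spikes_by_trial:
            g = spikes_by_trial[tid]
            for nid, gg in g.groupby("neuron_id"):
                spikes[str(nid)] = np.asarray(gg["spike_time"], dtype=float)
        licks = (np.asarray(licks_by_trial[tid]["lick_time"], dtype=float)
                 if tid in licks_by_trial else np.empty(0))
        trials.append(Trial(trial_id=tid, value_label=str(row.value_label),
                            condition=str(row.condition),
                            cs_location=str(row.cs_location),
                            events=ev, spikes=spikes, licks=licks))

    session = Session(
        trials=trials,
        neuron_ids=[str(n) for n in meta["neuron_ids"]],
        stimulus=StimulusSpec(**meta["stimulus"]),
        timing=TimingConfig(**meta["timing"]),
        block_start=int(meta["block_start"]),
    )
    session.validate()
    return session


def write_saccades(records: List[SaccadeRecord], path: Union[str, os.PathLike]) -> None:
    """Write saccade records to a standalone ``saccades.csv``."""
    rows = []
    for r in records:
        r.validate()
        rows.append((r.condition, r.target_direction, r.latency_ms))
    rows.sort()
    _write_csv(pd.DataFrame(rows, columns=_SACCADE_COLS), Path(path))


def read_saccades(path: Union[str, os.PathLike]) -> List[SaccadeRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _SACCADE_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"saccades.csv: missing column(s) {missing}")
    records = []
    for row in df.itertuples(index=False):
        rec = SaccadeRecord(condition=str(row.condition),
                            target_direction=float(row.target_direction),
                            latency_ms=float(row.latency_ms))
        rec.validate()
        records.append(rec)
    return records
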