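#!/usr/bin/env python
"""Simulate the synthetic experiment: nine two-block recording sessions
(one putative DA neuron each, ~60 control + 60 inactivation trials) plus a
visually guided saccade dataset with a 53 ms latency shift confined to the
45 deg target direction.

Raw session files are large, so they go under scratch/; a small manifest
with the generative ground truth goes under results/.
"""

import argparse
import json
from pathlib import Path

from dacue.io import write_saccades, write_session
from dacue.synth import SynthParams, generate_saccades, generate_session

ROOT = Path(__file__).resolve().parents[1]
N_SESSIONS = 9


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "experiment")
    ap.add_argument("--n-saccades", type=int, default=60)
    args = ap.parse_args()

    params = SynthParams()
    manifest = {"seed": args.seed, "n_sessions": N_SESSIONS,
                "params": params.to_dict(), "sessions": []}
    for i in range(N_SESSIONS):
        session_seed = args.seed * 1000 + i
        session = generate_session(params, session_seed)
        sdir = args.out / f"s{i + 1:02d}"
        write_session(session, sdir)
        n_spikes = sum(t.spikes["n1"].size for t in session.trials)
        manifest["sessions"].append({"dir": sdir.name, "seed": session_seed,
                                     "n_trials": len(session.trials),
                                     "n_spikes": n_spikes})
        print(f"{sdir.name}: {len(session.trials)} trials, {n_spikes} spikes")

    saccades = generate_saccades(params.saccade_model, args.n_saccades, args.seed)
    write_saccades(saccades, args.out / "saccades.csv")
    print(f"saccades: {len(saccades)} records "
          f"({args.n_saccades} per condition x direction)")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    with open(results / "01_simulate_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    print(f"wrote manifest to {results / '01_simulate_manifest.json'}")


if __name__ == "__main__":
    main()
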