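#!/usr/bin/env python
"""Compute excess-interrelation networks and detect core channels.

For every epoch of the simulated cohort (01_simulate_cohort.py): slide
8-s windows in 1-s steps, compute the surrogate-corrected non-linear
excess matrix per window, average over the epoch, collapse to node
strengths and select the core by the largest-gap rule. Writes the
epoch-averaged matrices, node strengths, detected cores and the
segment-vs-average similarity traces under results/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from excessnet.pipeline import analyze_epoch
from excessnet.preprocess import read_epoch

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
COHORT = RESULTS / "cohort"
SCRATCH = ROOT / "scratch" / "cohort"

ANALYSIS_SEED = 7
MAX_ITER = 10  # IAAFT refinement cap; see docs/methods.md


def main() -> None:
    manifest = json.loads((COHORT / "manifest.json").read_text())
    strength_rows, core_rows, sim_rows = [], [], []
    for entry in manifest["patients"]:
        pid = entry["patient"]
        epoch = read_epoch(SCRATCH / f"{pid}_epoch.csv")
        res = analyze_epoch(epoch, seed=ANALYSIS_SEED, max_iter=MAX_ITER)
        res.average.to_csv(RESULTS / f"{pid}_excess_average.csv")
        for ch, s in res.strengths.as_dict().items():
            strength_rows.append(dict(patient=pid, channel=ch, strength=s))
        core_rows.append(dict(
            patient=pid,
            core=",".join(sorted(res.core.channels)),
            planted=",".join(entry["planted_core"]),
            exact_recovery=set(res.core.channels) == set(entry["planted_core"]),
        ))
        for m, r in zip(res.window_matrices, res.similarity):
            sim_rows.append(dict(patient=pid, t_start=m.window[0], similarity=r))
    pd.DataFrame(strength_rows).to_csv(RESULTS / "node_strengths.csv", index=False)
    cores = pd.DataFrame(core_rows)
    cores.to_csv(RESULTS / "cores.csv", index=False)
    pd.DataFrame(sim_rows).to_csv(RESULTS / "segment_similarity.csv", index=False)
    rate = cores.exact_recovery.mean()
    print(f"analyzed {len(core_rows)} epochs; exact planted-core recovery in "
          f"{rate:.0%} of epochs")
    print(f"matrices, strengths, cores, similarity traces -> {RESULTS}")


if __name__ == "__main__":
    main()
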