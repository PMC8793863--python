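#!/usr/bin/env python
"""Simulate a preictal iEEG cohort with planted coupling structure.

Generates an aligned synthetic cohort (favorable patients: planted
non-linear core and SOZ inside the resected tissue; unfavorable: core
disjoint from it; plus patients without surgery), writes annotations and
a manifest under results/cohort/, and the raw signal matrices under
scratch/cohort/ (they are large and regenerable from the manifest seed).

The cohort is scaled down from the clinical corpus (99 epochs of
110-200 s, 50-60 channels) to keep the run interactive; all structural
features are preserved. Event waveforms are recorded in the annotations
but not injected into the signals, so the network stage isolates the
planted non-linear coupling (see docs/methods.md on the event-injection
confound).
"""

import json
from pathlib import Path

from excessnet.preprocess import write_annotations, write_epoch
from excessnet.synthetic import generate_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results" / "cohort"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "cohort"

COHORT_SEED = 20240917
N_FAVORABLE, N_UNFAVORABLE, N_NOSURGERY = 6, 6, 3
N_CHANNELS, DURATION = 10, 32.0


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    records = generate_cohort(
        N_FAVORABLE, N_UNFAVORABLE, N_NOSURGERY, scenario="aligned",
        seed=COHORT_SEED, n_channels=N_CHANNELS, duration=DURATION,
        core_size=3, linear_size=2, inject=False,
    )
    manifest = []
    for i, (epoch, ann, truth) in enumerate(records):
        pid = f"p{i:02d}"
        write_epoch(SCRATCH / f"{pid}_epoch.csv", epoch)
        write_annotations(RESULTS / f"{pid}_annotations.json", ann)
        manifest.append({
            "patient": pid,
            "outcome": truth.outcome,
            "n_events": len(ann.events),
            "planted_core": sorted(truth.planted_core),
            "linear_group": sorted(truth.linear_group),
            "soz": sorted(truth.soz),
            "rbt": None if truth.rbt is None else sorted(truth.rbt),
            "epoch_seed": truth.seed,
        })
    with open(RESULTS / "manifest.json", "w") as fh:
        json.dump({"cohort_seed": COHORT_SEED, "n_channels": N_CHANNELS,
                   "duration_s": DURATION, "patients": manifest}, fh, indent=1)
    n_ev = sum(m["n_events"] for m in manifest)
    print(f"simulated {len(records)} patients ({N_FAVORABLE} favorable, "
          f"{N_UNFAVORABLE} unfavorable, {N_NOSURGERY} without surgery), "
          f"{n_ev} epileptiform events")
    print(f"annotations + manifest -> {RESULTS}")
    print(f"signal matrices -> {SCRATCH}")


if __name__ == "__main__":
    main()
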