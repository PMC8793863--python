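#!/usr/bin/env python
"""Channel-set prediction: events / SOZ / core against SOZ / RBT / core.

For each epoch of the simulated cohort, labels every artifact-free
channel TP/FP/FN/TN for the six predictive->target pairings
(events->SOZ, events->RBT, events->core, SOZ->RBT, core->SOZ,
core->RBT; events also per type), micro-pools counts over events, and
writes the epoch-level precision/recall/F1 table.
"""

import json
from pathlib import Path

import pandas as pd

from excessnet.network import CoreSet
from excessnet.prediction import evaluate_pairings
from excessnet.preprocess import read_annotations, read_epoch, restrict_to_usable

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
COHORT = RESULTS / "cohort"
SCRATCH = ROOT / "scratch" / "cohort"


def main() -> None:
    manifest = json.loads((COHORT / "manifest.json").read_text())
    cores = pd.read_csv(RESULTS / "cores.csv", keep_default_na=False)
    core_by_pid = {
        r.patient: frozenset(c for c in str(r.core).split(",") if c)
        for r in cores.itertuples()
    }
    tables = []
    for entry in manifest["patients"]:
        pid = entry["patient"]
        epoch = read_epoch(SCRATCH / f"{pid}_epoch.csv")
        ann = restrict_to_usable(read_annotations(COHORT / f"{pid}_annotations.json"), epoch)
        table = evaluate_pairings(ann, core_by_pid[pid], frozenset(epoch.usable_labels))
        table.insert(0, "patient", pid)
        table["outcome"] = ann.outcome
        tables.append(table)
    out = pd.concat(tables, ignore_index=True)
    out.to_csv(RESULTS / "predictions.csv", index=False)
    agg = out[(out.event_type.isin(["", "all"])) & out.available]
    summary = agg.groupby("pairing")[["precision", "recall", "f1"]].median()
    print("epoch-level accuracy (medians over available epochs):")
    print(summary.round(3).to_string())
    print(f"full table -> {RESULTS / 'predictions.csv'}")


if __name__ == "__main__":
    main()
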