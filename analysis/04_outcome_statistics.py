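#!/usr/bin/env python
"""Outcome-group statistics over the channel-set prediction table.

Contrasts each accuracy quantifier between the favorable and unfavorable
surgery-outcome groups (two-sided Mann-Whitney U; patients without
surgery summarized but never tested), applies Bonferroni correction for
the six-pairing family (0.01/6 -> 0.0017; trends 0.05/6 -> 0.0083), and
compares event-type proportions between the outcome groups with a
Chi-squared test. Writes the report table as CSV and formatted text.
"""

import json
from pathlib import Path

import pandas as pd

from excessnet.preprocess import EVENT_TYPES
from excessnet.stats_report import (
    comparison_table,
    event_type_proportion_test,
    format_comparison_table,
    outcome_contrast,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
COHORT = RESULTS / "cohort"


def main() -> None:
    table = pd.read_csv(RESULTS / "predictions.csv", keep_default_na=False)
    table["event_type"] = table["event_type"].fillna("")
    table["available"] = table["available"].astype(bool)

    comps = outcome_contrast(table)
    comparison_table(comps).to_csv(RESULTS / "outcome_contrasts.csv", index=False)
    text = format_comparison_table(comps)
    (RESULTS / "outcome_contrasts.txt").write_text(text + "\n")
    print(text)

    # event-type proportions, favorable vs unfavorable
    manifest = json.loads((COHORT / "manifest.json").read_text())
    counts = {"favorable": dict.fromkeys(EVENT_TYPES, 0),
              "unfavorable": dict.fromkeys(EVENT_TYPES, 0)}
    for entry in manifest["patients"]:
        if entry["outcome"] not in counts:
            continue
        doc = json.loads((COHORT / f"{entry['patient']}_annotations.json").read_text())
        for ev in doc["events"]:
            counts[entry["outcome"]][ev["type"]] += 1
    a = [counts["favorable"][t] for t in EVENT_TYPES]
    b = [counts["unfavorable"][t] for t in EVENT_TYPES]
    p = event_type_proportion_test(a, b)
    print(f"\nevent-type proportions favorable {a} vs unfavorable {b}: "
          f"Chi-squared p = {p:.4g}")
    print(f"report tables -> {RESULTS}")


if __name__ == "__main__":
    main()
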