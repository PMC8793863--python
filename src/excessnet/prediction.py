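"""Channel-set prediction: confusion counts and TN-independent accuracy.

One channel set (events' affected channels, SOZ, or detected core) is used
to predict another (SOZ, RBT, or core). Every channel of the epoch's
artifact-free universe is labelled TP (in both sets), FP (predictive
only), FN (target only) or TN (neither). Because the target sets comprise
a small minority of channels, TN dominates; accuracy is therefore reported
with the TN-independent precision, recall and their harmonic mean (F1),
using the 0/0 -> 0 convention so rank statistics over epochs are defined.

Events are pooled per epoch by summing TP/FP/FN/TN over events first and
computing the ratios once (micro-pooling), not by averaging per-event
scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .preprocess import EVENT_TYPES, AnnotationSet, EventAnnotation
from .network import CoreSet

PAIRINGS = (
    ("events", "soz"),
    ("events", "rbt"),
    ("events", "core"),
    ("soz", "rbt"),
    ("core", "soz"),
    ("core", "rbt"),
)


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class AccuracyTriple:
    precision: float
    recall: float
    f1: float


def confusion(
    predictive: frozenset[str] | set[str],
    target: frozenset[str] | set[str],
    universe: frozenset[str] | set[str],
) -> ConfusionCounts:
    """Four-way channel labelling of ``universe`` by the two sets."""
    predictive, target, universe = set(predictive), set(target), set(universe)
    if not predictive <= universe:
        raise ValueError("predictive set not contained in universe")
    if not target <= universe:
        raise ValueError("target set not contained in universe")
    tp = len(predictive & target)
    fp = len(predictive - target)
    fn = len(target - predictive)
    tn = len(universe - predictive - target)
    return ConfusionCounts(tp, fp, fn, tn)


def accuracy(counts: ConfusionCounts) -> AccuracyTriple:
    """Precision, recall and F1 with the 0/0 -> 0 convention."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return AccuracyTriple(p, r, f1)


def pool_events(
    events: list[EventAnnotation],
    type_filter: str,
    target: frozenset[str] | set[str],
    universe: frozenset[str] | set[str],
) -> tuple[ConfusionCounts, AccuracyTriple]:
    """Micro-pool the event->target prediction over qualifying events.

    Each qualifying event's affected channels form the predictive set;
    confusion counts are computed per event against the fixed target and
    summed, then the accuracy ratios are taken once. Event channels
    outside the universe (annotations on artifact channels) are dropped
    with a warning. Zero qualifying events give all-zero counts and
    (0, 0, 0).
    """
    if type_filter != "all" and type_filter not in EVENT_TYPES:
        raise ValueError(f"unknown event type filter {type_filter!r}")
    universe = set(universe)
    pooled = ConfusionCounts()
    for ev in events:
        if type_filter != "all" and ev.event_type != type_filter:
            continue
        chans = set(ev.channels)
        if not chans <= universe:
            warnings.warn(
                f"event at {ev.t_start:.2f}s has channels outside the universe; dropped",
                stacklevel=2,
            )
            chans &= universe
        pooled = pooled + confusion(chans, target, universe)
    return pooled, accuracy(pooled)


def evaluate_pairings(
    annotations: AnnotationSet,
    core: CoreSet | frozenset[str],
    universe: frozenset[str] | set[str],
) -> pd.DataFrame:
    """Epoch-level accuracy table for the six predictive->target pairings.

    Rows follow the order events->SOZ, events->RBT, events->core,
    SOZ->RBT, core->SOZ, core->RBT; the three event rows additionally
    appear broken down per event type. Pairings targeting the RBT of a
    patient without surgery are emitted with ``available=False`` and NaN
    metrics.
    """
    universe = set(universe)
    core_set = set(core.channels if isinstance(core, CoreSet) else core) & universe
    soz = set(annotations.soz) & universe
    rbt = None if annotations.rbt is None else set(annotations.rbt) & universe
    targets = {"soz": soz, "rbt": rbt, "core": core_set}

    rows = []

    def add(pairing: str, event_type: str, counts: ConfusionCounts | None) -> None:
        if counts is None:
            rows.append(
                dict(pairing=pairing, event_type=event_type, available=False,
                     tp=0, fp=0, fn=0, tn=0,
                     precision=float("nan"), recall=float("nan"), f1=float("nan"))
            )
            return
        acc = accuracy(counts)
        rows.append(
            dict(pairing=pairing, event_type=event_type, available=True,
                 tp=counts.tp, fp=counts.fp, fn=counts.fn, tn=counts.tn,
                 precision=acc.precision, recall=acc.recall, f1=acc.f1)
        )

    for pred, targ in PAIRINGS:
        pairing = f"{pred}->{targ}"
        target = targets[targ]
        if pred == "events":
            for etype in ("all",) + EVENT_TYPES:
                if target is None:
                    add(pairing, etype, None)
                else:
                    counts, _ = pool_events(annotations.events, etype, target, universe)
                    add(pairing, etype, counts)
        else:
            predictive = targets[pred]
            if target is None:
                add(pairing, "", None)
            else:
                add(pairing, "", confusion(predictive, target, universe))
    return pd.DataFrame(rows)
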