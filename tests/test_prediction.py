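import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from excessnet.prediction import (
    AccuracyTriple,
    ConfusionCounts,
    accuracy,
    confusion,
    evaluate_pairings,
    pool_events,
)
from excessnet.preprocess import AnnotationSet, EventAnnotation
from excessnet.network import CoreSet


def brute_confusion(predictive, target, universe):
    """Oracle: label every channel one by one."""
    tp = fp = fn = tn = 0
    for ch in universe:
        if ch in predictive and ch in target:
            tp += 1
        elif ch in predictive:
            fp += 1
        elif ch in target:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


class TestConfusion:
    def test_enumerated_example(self):
        c = confusion({"A", "B"}, {"B", "C"}, {"A", "B", "C", "D"})
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_identity_prediction(self):
        c = confusion({"A", "B"}, {"A", "B"}, {"A", "B", "C"})
        assert c.fp == 0 and c.fn == 0

    def test_empty_predictor(self):
        c = confusion(set(), {"A", "B"}, {"A", "B", "C"})
        assert (c.tp, c.fp, c.fn) == (0, 0, 2)

    def test_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            confusion({"X"}, {"A"}, {"A", "B"})

    def test_counts_partition_universe(self, rng):
        chans = [f"c{i}" for i in range(12)]
        for _ in range(50):
            pred = set(rng.choice(chans, rng.integers(0, 8), replace=False))
            targ = set(rng.choice(chans, rng.integers(0, 8), replace=False))
            c = confusion(pred, targ, chans)
            assert c.total == 12
            assert (c.tp, c.fp, c.fn, c.tn) == brute_confusion(pred, targ, chans)


class TestAccuracy:
    def test_balanced_case(self):
        t = accuracy(ConfusionCounts(1, 1, 1, 1))
        assert (t.precision, t.recall, t.f1) == (0.5, 0.5, 0.5)

    def test_harmonic_mean(self):
        t = accuracy(ConfusionCounts(tp=1, fp=0, fn=2, tn=0))
        assert t.precision == 1.0
        assert t.recall == pytest.approx(1 / 3)
        assert t.f1 == pytest.approx(0.5)

    def test_zero_over_zero_convention(self):
        t = accuracy(ConfusionCounts(tp=0, fp=0, fn=3, tn=0))
        assert (t.precision, t.recall, t.f1) == (0.0, 0.0, 0.0)

    def test_tn_independence(self, rng):
        for _ in range(20):
            tp, fp, fn = rng.integers(0, 10, 3)
            a = accuracy(ConfusionCounts(tp, fp, fn, 0))
            b = accuracy(ConfusionCounts(tp, fp, fn, 1000))
            assert (a.precision, a.recall, a.f1) == (b.precision, b.recall, b.f1)

    @given(st.integers(1, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=100, deadline=None)
    def test_f1_between_precision_and_recall(self, tp, fp, fn):
        t = accuracy(ConfusionCounts(tp, fp, fn, 0))
        if t.precision > 0 and t.recall > 0:
            assert min(t.precision, t.recall) - 1e-12 <= t.f1 <= max(t.precision, t.recall) + 1e-12


class TestPoolEvents:
    universe = frozenset({"A", "B", "C", "D"})

    def _event(self, chans, etype="spike", t=0.0):
        return EventAnnotation(etype, t, t + 0.05, frozenset(chans))

    def test_single_perfect_event(self):
        counts, acc = pool_events([self._event({"A", "B"})], "all", {"A", "B"}, self.universe)
        assert acc.precision == 1.0 and acc.recall == 1.0

    def test_duplicate_events_leave_ratios_unchanged(self):
        ev = self._event({"A"})
        _, one = pool_events([ev], "all", {"A", "B"}, self.universe)
        _, two = pool_events([ev, ev], "all", {"A", "B"}, self.universe)
        assert (one.precision, one.recall, one.f1) == (two.precision, two.recall, two.f1)

    def test_pooled_counts_enumerated(self):
        events = [self._event({"A"}), self._event({"B"}, t=1.0)]
        counts, acc = pool_events(events, "all", {"A"}, {"A", "B"})
        assert (counts.tp, counts.fp, counts.fn) == (1, 1, 1)
        assert (acc.precision, acc.recall, acc.f1) == (0.5, 0.5, 0.5)

    def test_micro_pooling_not_score_average(self):
        # event 1: tp=1 fp=0 (P=1); event 2: tp=0 fp=3 fn=1 (P=0)
        # micro: P = 1/4; macro mean would be 1/2
        events = [self._event({"A"}), self._event({"B", "C", "D"}, t=1.0)]
        counts, acc = pool_events(events, "all", {"A"}, self.universe)
        assert acc.precision == pytest.approx(0.25)

    def test_type_filter(self):
        events = [self._event({"A"}, "spike"), self._event({"B"}, "slow_wave", 1.0)]
        counts, _ = pool_events(events, "spike", {"A"}, self.universe)
        assert counts.tp == 1 and counts.fp == 0

    def test_no_qualifying_events(self):
        _, acc = pool_events([], "all", {"A"}, self.universe)
        assert (acc.precision, acc.recall, acc.f1) == (0.0, 0.0, 0.0)

    def test_channels_outside_universe_dropped_with_warning(self):
        ev = self._event({"A", "X"})
        with pytest.warns(UserWarning):
            counts, _ = pool_events([ev], "all", {"A"}, self.universe)
        assert counts.tp == 1 and counts.fp == 0


class TestEvaluatePairings:
    universe = frozenset({"A", "B", "C", "D", "E"})

    def _annotations(self, rbt={"A", "B"}, outcome="favorable"):
        return AnnotationSet(
            events=[
                EventAnnotation("spike", 0.0, 0.05, frozenset({"A"})),
                EventAnnotation("slow_wave", 1.0, 1.5, frozenset({"B", "C"})),
            ],
            soz=frozenset({"A", "B"}),
            rbt=None if rbt is None else frozenset(rbt),
            outcome=outcome,
        )

    def test_perfect_alignment_rows(self):
        ann = self._annotations(rbt={"A", "B"})
        core = CoreSet(frozenset({"A", "B"}), 2, 2)
        table = evaluate_pairings(ann, core, self.universe)
        for pairing in ("soz->rbt", "core->soz", "core->rbt"):
            row = table[(table.pairing == pairing)].iloc[0]
            assert (row.precision, row.recall, row.f1) == (1.0, 1.0, 1.0)

    def test_empty_core_rows_zero(self):
        ann = self._annotations()
        table = evaluate_pairings(ann, frozenset(), self.universe)
        row = table[(table.pairing == "core->rbt")].iloc[0]
        assert (row.precision, row.recall, row.f1) == (0.0, 0.0, 0.0)

    def test_missing_rbt_marked_unavailable(self):
        ann = self._annotations(rbt=None, outcome="none")
        table = evaluate_pairings(ann, frozenset({"A"}), self.universe)
        rbt_rows = table[table.pairing.str.endswith("->rbt")]
        assert not rbt_rows.available.any()
        assert rbt_rows.precision.isna().all()
        other = table[~table.pairing.str.endswith("->rbt")]
        assert other.available.all()

    def test_row_order_and_event_breakdown(self):
        table = evaluate_pairings(self._annotations(), frozenset({"A"}), self.universe)
        pairings = list(dict.fromkeys(table.pairing))
        assert pairings == [
            "events->soz", "events->rbt", "events->core",
            "soz->rbt", "core->soz", "core->rbt",
        ]
        ev_rows = table[table.pairing == "events->soz"]
        assert list(ev_rows.event_type) == [
            "all", "spike", "slow_wave", "sharp_wave", "fast_oscillation"
        ]

    def test_matches_brute_force_enumeration(self, rng):
        chans = [f"c{i}" for i in range(10)]
        for trial in range(25):
            soz = frozenset(rng.choice(chans, 3, replace=False))
            rbt = frozenset(rng.choice(chans, 4, replace=False))
            core = frozenset(rng.choice(chans, 2, replace=False))
            events = [
                EventAnnotation("spike", float(k), float(k) + 0.05,
                                frozenset(rng.choice(chans, rng.integers(1, 4), replace=False)))
                for k in range(3)
            ]
            ann = AnnotationSet(events=events, soz=soz, rbt=rbt, outcome="favorable")
            table = evaluate_pairings(ann, core, frozenset(chans))
            # oracle for events->rbt, all types pooled
            tp = fp = fn = tn = 0
            for ev in events:
                a, b, c, d = brute_confusion(ev.channels, rbt, chans)
                tp, fp, fn, tn = tp + a, fp + b, fn + c, tn + d
            row = table[(table.pairing == "events->rbt") & (table.event_type == "all")].iloc[0]
            assert (row.tp, row.fp, row.fn, row.tn) == (tp, fp, fn, tn)
            if tp + fp:
                assert row.precision == pytest.approx(tp / (tp + fp))
            # oracle for core->soz
            row = table[table.pairing == "core->soz"].iloc[0]
            assert (row.tp, row.fp, row.fn, row.tn) == brute_confusion(core, soz, chans)
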