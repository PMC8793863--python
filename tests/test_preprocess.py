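import json

import numpy as np
import pytest
from scipy import signal

from excessnet.preprocess import (
    AnnotationSet,
    EpochRecording,
    EventAnnotation,
    ValidationError,
    bandpass_filter,
    read_annotations,
    read_epoch,
    rereference_median,
    restrict_to_usable,
    write_annotations,
    write_epoch,
)

from conftest import write_minimal_edf


class TestEpochRecording:
    def test_shape_bookkeeping(self, small_epoch):
        assert small_epoch.n_samples == 5120
        assert small_epoch.duration == 10.0

    def test_duplicate_labels_rejected(self, rng):
        with pytest.raises(ValidationError, match="duplicate"):
            EpochRecording(["A", "A"], rng.standard_normal((2, 512)), 512.0)

    def test_needs_two_usable_channels(self, rng):
        with pytest.raises(ValidationError):
            EpochRecording(["A", "B"], rng.standard_normal((2, 512)), 512.0,
                           artifact_channels={"B"})

    def test_artifact_channels_flagged_not_dropped(self, rng):
        ep = EpochRecording(["A", "B", "C"], rng.standard_normal((3, 512)), 512.0,
                            artifact_channels={"B"})
        assert ep.n_channels == 3
        assert ep.usable_labels == ["A", "C"]
        assert ep.usable_samples().shape == (2, 512)


class TestMatrixIO:
    def test_round_trip(self, tmp_path, small_epoch):
        path = tmp_path / "epoch.csv"
        write_epoch(path, small_epoch)
        back = read_epoch(path, format="matrix")
        assert back.channel_labels == small_epoch.channel_labels
        assert back.fs == small_epoch.fs
        np.testing.assert_allclose(back.samples, small_epoch.samples, rtol=1e-9)

    def test_header_echoed(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("# fs=1024\nw,x,y,z\n" + "\n".join(["0,1,2", "3,4,5", "6,7,8", "9,0,1"]))
        ep = read_epoch(path)
        assert ep.fs == 1024
        assert ep.channel_labels == ["w", "x", "y", "z"]

    def test_artifact_round_trip(self, tmp_path, rng):
        ep = EpochRecording(["A", "B", "C"], rng.standard_normal((3, 64)), 256.0,
                            artifact_channels={"C"})
        write_epoch(tmp_path / "a.csv", ep)
        back = read_epoch(tmp_path / "a.csv")
        assert back.artifact_channels == frozenset({"C"})

    def test_missing_fs_header(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n3,4\n")
        with pytest.raises(ValidationError, match="fs"):
            read_epoch(path, format="matrix")


class TestEdf:
    def test_read_edf(self, tmp_path, rng):
        fs = 256.0
        samples = 50.0 * rng.standard_normal((3, int(4 * fs)))
        path = tmp_path / "rec.edf"
        write_minimal_edf(path, ["TAR1", "TAR2", "TAR3"], samples, fs)
        ep = read_epoch(path, format="edf")
        assert ep.channel_labels == ["TAR1", "TAR2", "TAR3"]
        assert ep.fs == fs
        # 16-bit quantization at ~0.06 uV/bit
        np.testing.assert_allclose(ep.samples, samples, atol=0.1)

    def test_single_channel_edf_rejected(self, tmp_path, rng):
        path = tmp_path / "one.edf"
        write_minimal_edf(path, ["ONLY"], 10 * rng.standard_normal((1, 256)), 256.0)
        with pytest.raises(ValidationError):
            read_epoch(path, format="edf")


class TestRereferenceMedian:
    def test_identical_channels_zero_out(self, rng):
        row = rng.standard_normal(512)
        ep = EpochRecording(["A", "B", "C"], np.tile(row, (3, 1)), 512.0)
        out = rereference_median(ep)
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_constant_channels_hand_computed(self):
        samples = np.tile(np.array([[1.0], [2.0], [100.0]]), (1, 512))
        ep = EpochRecording(["A", "B", "C"], samples, 512.0)
        out = rereference_median(ep)
        np.testing.assert_allclose(out.samples[:, 0], [-1.0, 0.0, 98.0])

    def test_offset_invariance(self, small_epoch):
        shifted = EpochRecording(
            small_epoch.channel_labels, small_epoch.samples + 42.0, small_epoch.fs
        )
        np.testing.assert_allclose(
            rereference_median(small_epoch).samples,
            rereference_median(shifted).samples,
            atol=1e-9,
        )

    def test_idempotent(self, small_epoch):
        once = rereference_median(small_epoch)
        twice = rereference_median(once)
        np.testing.assert_allclose(once.samples, twice.samples, atol=1e-9)

    def test_artifact_channels_excluded_from_median(self, rng):
        base = rng.standard_normal((2, 256))
        huge = np.full((1, 256), 1e6)
        ep = EpochRecording(
            ["A", "B", "BAD"], np.vstack([base, huge]), 512.0, artifact_channels={"BAD"}
        )
        out = rereference_median(ep)
        assert np.max(np.abs(out.samples[:2])) < 1e3  # unaffected by the artifact channel


class TestBandpassFilter:
    def _tone(self, freq, fs, dur=8.0):
        t = np.arange(int(dur * fs)) / fs
        return np.sin(2 * np.pi * freq * t)

    @staticmethod
    def _amplitude_at(x, freq, fs):
        # projection onto the tone frequency; insensitive to the slow
        # high-pass transients the 0.5 Hz corner leaves at the edges
        t = np.arange(x.size) / fs
        c = np.cos(2 * np.pi * freq * t)
        s = np.sin(2 * np.pi * freq * t)
        return 2 * np.hypot(np.dot(x, c), np.dot(x, s)) / x.size

    def test_passband_tone_preserved(self):
        fs = 512.0
        tone = self._tone(50.0, fs)
        ep = EpochRecording(["A", "B"], np.vstack([tone, tone]), fs)
        out = bandpass_filter(ep)
        mid = slice(1024, -1024)
        a = self._amplitude_at(out.samples[0][mid], 50.0, fs)
        assert a == pytest.approx(1.0, abs=0.01)  # <1% attenuation in-band

    def test_stopband_tone_suppressed(self):
        fs = 1024.0
        tone = self._tone(300.0, fs)
        ep = EpochRecording(["A", "B"], np.vstack([tone, tone]), fs)
        out = bandpass_filter(ep)
        mid = slice(2048, -2048)
        a = self._amplitude_at(out.samples[0][mid], 300.0, fs)
        assert a < 0.1  # >90% amplitude attenuation beyond the 150 Hz corner

    def test_zero_in_zero_out(self):
        ep = EpochRecording(["A", "B"], np.zeros((2, 2048)), 512.0)
        out = bandpass_filter(ep)
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_high_cutoff_above_nyquist_rejected(self, small_epoch):
        with pytest.raises(ValidationError, match="Nyquist"):
            bandpass_filter(small_epoch, high=300.0)  # fs=512 -> Nyquist 256

    def test_zero_group_delay(self):
        # a band-limited pulse must not be shifted by the forward-backward filter
        fs = 512.0
        n = 4096
        pulse = signal.gausspulse(np.arange(n) / fs - 4.0, fc=20.0)
        ep = EpochRecording(["A", "B"], np.vstack([pulse, pulse]), fs)
        out = bandpass_filter(ep)
        xc = signal.correlate(out.samples[0], pulse, mode="full")
        assert np.argmax(np.abs(xc)) == n - 1  # peak at lag 0

    def test_single_pass_shifts_but_same_shape(self):
        fs = 512.0
        pulse = signal.gausspulse(np.arange(2048) / fs - 2.0, fc=20.0)
        ep = EpochRecording(["A", "B"], np.vstack([pulse, pulse]), fs)
        out = bandpass_filter(ep, zero_phase=False)
        assert out.samples.shape == ep.samples.shape


class TestAnnotations:
    def _doc(self):
        return {
            "events": [
                {"type": "spike", "t_start": 1.0, "t_end": 1.05, "channels": ["A"]},
                {"type": "spike", "t_start": 2.0, "t_end": 2.04, "channels": ["B"]},
            ],
            "soz": ["A"],
            "rbt": ["A", "B"],
            "outcome": "favorable",
        }

    def test_parse_counts(self, tmp_path):
        path = tmp_path / "ann.json"
        path.write_text(json.dumps(self._doc()))
        ann = read_annotations(path)
        assert len(ann.events) == 2
        assert ann.soz == {"A"}

    def test_unknown_event_type_rejected(self, tmp_path):
        doc = self._doc()
        doc["events"][0]["type"] = "ripple"
        path = tmp_path / "ann.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ValidationError, match="ripple"):
            read_annotations(path)

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValidationError):
            EventAnnotation("spike", 2.0, 1.0, frozenset({"A"}))

    def test_no_surgery_patient_valid(self, tmp_path):
        path = tmp_path / "ann.json"
        path.write_text(json.dumps({"events": [], "soz": ["A"], "rbt": None, "outcome": "none"}))
        ann = read_annotations(path)
        assert ann.rbt is None and ann.events == []

    def test_outcome_none_with_rbt_rejected(self):
        with pytest.raises(ValidationError):
            AnnotationSet(events=[], soz=frozenset(), rbt=frozenset({"A"}), outcome="none")

    def test_round_trip_with_core(self, tmp_path):
        path = tmp_path / "ann.json"
        write_annotations(
            path,
            AnnotationSet(
                events=[EventAnnotation("slow_wave", 0.5, 1.2, frozenset({"A", "B"}))],
                soz=frozenset({"A"}), rbt=frozenset({"B"}), outcome="unfavorable",
            ),
            core=frozenset({"A"}),
        )
        doc = json.loads(path.read_text())
        assert doc["core"] == ["A"]
        back = read_annotations(path)
        assert back.events[0].channels == {"A", "B"}

    def test_restrict_to_usable_drops_artifact_events(self, rng):
        ep = EpochRecording(["A", "B", "BAD"], rng.standard_normal((3, 512)), 512.0,
                            artifact_channels={"BAD"})
        ann = AnnotationSet(
            events=[
                EventAnnotation("spike", 0.1, 0.15, frozenset({"BAD"})),
                EventAnnotation("spike", 0.2, 0.25, frozenset({"A", "BAD"})),
            ],
            soz=frozenset({"A", "BAD"}),
        )
        with pytest.warns(UserWarning):
            out = restrict_to_usable(ann, ep)
        assert len(out.events) == 1
        assert out.events[0].channels == {"A"}
        assert out.soz == {"A"}

    def test_validate_against_epoch(self, small_epoch, tmp_path):
        doc = self._doc()
        doc["soz"] = ["NOPE"]
        path = tmp_path / "ann.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ValidationError, match="SOZ"):
            read_annotations(path, epoch=small_epoch)
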