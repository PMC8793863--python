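"""Epoch and annotation I/O, re-referencing, band-pass filtering.

Raw intracranial EEG epochs enter the pipeline here. Channels are
re-referenced against the per-sample median of all artifact-free channels
and band-pass filtered 0.5–150 Hz with a fourth-order Butterworth design
applied forward-backward (zero phase), matching standard clinical
preprocessing of preictal iEEG.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal

EVENT_TYPES = ("spike", "slow_wave", "sharp_wave", "fast_oscillation")

OUTCOMES = ("favorable", "unfavorable", "none")


class ValidationError(ValueError):
    """Raised when an epoch or annotation violates its contract."""


@dataclass
class EpochRecording:
    """A multichannel iEEG epoch.

    Attributes
    ----------
    channel_labels : list of str
        Unique channel names, ordered as the rows of ``samples``.
    samples : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz (512 or 1024 in the clinical recordings).
    artifact_channels : frozenset of str
        Channels flagged as artifact-corrupted. They are carried (so
        indexing into annotations stays stable) but excluded from every
        downstream computation.
    """

    channel_labels: list[str]
    samples: np.ndarray
    fs: float
    artifact_channels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.channel_labels = list(self.channel_labels)
        self.samples = np.asarray(self.samples, dtype=float)
        self.artifact_channels = frozenset(self.artifact_channels)
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValidationError("duplicate channel labels")
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D [channels x samples] array")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValidationError(
                f"{len(self.channel_labels)} labels but {self.samples.shape[0]} sample rows"
            )
        if not self.fs > 0:
            raise ValidationError("sampling rate must be positive")
        if not self.artifact_channels <= set(self.channel_labels):
            raise ValidationError("artifact_channels not a subset of channel_labels")
        if len(self.usable_labels) < 2:
            raise ValidationError("need >= 2 artifact-free channels")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Epoch duration in seconds."""
        return self.n_samples / self.fs

    @property
    def usable_labels(self) -> list[str]:
        """Artifact-free channel labels, in recording order."""
        return [c for c in self.channel_labels if c not in self.artifact_channels]

    @property
    def usable_mask(self) -> np.ndarray:
        return np.array([c not in self.artifact_channels for c in self.channel_labels])

    def usable_samples(self) -> np.ndarray:
        """Rows of ``samples`` for artifact-free channels only."""
        return self.samples[self.usable_mask]


@dataclass(frozen=True)
class EventAnnotation:
    """One visually annotated epileptiform transient.

    ``event_type`` is one of spike (<70 ms), sharp_wave (70–200 ms),
    slow_wave, fast_oscillation (>30 Hz burst). Times are seconds from
    epoch start, half-open interval [t_start, t_end).
    """

    event_type: str
    t_start: float
    t_end: float
    channels: frozenset[str]

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(f"unknown event type {self.event_type!r}")
        if not (0 <= self.t_start < self.t_end):
            raise ValidationError("need 0 <= t_start < t_end")
        if not self.channels:
            raise ValidationError("event must affect at least one channel")
        object.__setattr__(self, "channels", frozenset(self.channels))

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class AnnotationSet:
    """Events plus the clinically defined channel sets of one epoch.

    ``soz`` is the seizure-onset zone; ``rbt`` the resected brain tissue
    (``None`` for patients without surgery); ``outcome`` the dichotomized
    Engel class (favorable = I–II, unfavorable = III–IV, none = no surgery).
    """

    events: list[EventAnnotation]
    soz: frozenset[str] = field(default_factory=frozenset)
    rbt: frozenset[str] | None = None
    outcome: str = "none"

    def __post_init__(self) -> None:
        self.events = list(self.events)
        self.soz = frozenset(self.soz)
        if self.rbt is not None:
            self.rbt = frozenset(self.rbt)
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"unknown outcome {self.outcome!r}")
        if self.outcome == "none" and self.rbt is not None:
            raise ValidationError("outcome 'none' implies no resected tissue set")

    def validate_against(self, epoch: EpochRecording) -> None:
        """Check channel-set containment and event timing against an epoch."""
        labels = set(epoch.channel_labels)
        if not self.soz <= labels:
            raise ValidationError("SOZ contains unknown channels")
        if self.rbt is not None and not self.rbt <= labels:
            raise ValidationError("RBT contains unknown channels")
        for ev in self.events:
            if ev.t_end > epoch.duration + 1e-9:
                raise ValidationError(f"event ends after epoch ({ev.t_end:.3f} s)")
            if not ev.channels <= labels:
                raise ValidationError("event channels not in epoch labels")


def restrict_to_usable(annotations: AnnotationSet, epoch: EpochRecording) -> AnnotationSet:
    """Drop artifact channels from every event's channel set.

    Events annotated exclusively on artifact channels are removed with a
    warning; the SOZ/RBT sets are likewise intersected with the usable
    channels.
    """
    usable = set(epoch.usable_labels)
    events = []
    for ev in annotations.events:
        kept = ev.channels & usable
        if not kept:
            warnings.warn(
                f"event at {ev.t_start:.2f}s lies entirely on artifact channels; dropped",
                stacklevel=2,
            )
            continue
        if kept != ev.channels:
            warnings.warn(
                f"event at {ev.t_start:.2f}s annotated on artifact channels; restricted",
                stacklevel=2,
            )
            ev = replace(ev, channels=frozenset(kept))
        events.append(ev)
    return AnnotationSet(
        events=events,
        soz=annotations.soz & usable,
        rbt=None if annotations.rbt is None else annotations.rbt & usable,
        outcome=annotations.outcome,
    )


# ---------------------------------------------------------------------------
# I/O

def read_epoch(path: str | Path, format: str | None = None) -> EpochRecording:
    """Read an epoch from EDF or the plain delimited-matrix format.

    The matrix dialect is: first line ``# fs=<Hz>`` (optionally followed by
    ``# artifacts=<comma list>``), one line of comma-separated channel
    labels, then one comma-separated row of samples per channel.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        return _read_edf(path)
    if format == "matrix":
        return _read_matrix(path)
    raise ValueError(f"unknown format {format!r}")


def _read_edf(path: Path) -> EpochRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    samples = raw.get_data() * 1e6  # mne returns volts
    return EpochRecording(
        channel_labels=list(raw.ch_names),
        samples=samples,
        fs=float(raw.info["sfreq"]),
    )


def _read_matrix(path: Path) -> EpochRecording:
    fs = None
    artifacts: list[str] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = []
    while lines and lines[0].lstrip().startswith("#"):
        header.append(lines.pop(0).lstrip("# ").strip())
    for item in header:
        if item.startswith("fs="):
            fs = float(item[3:])
        elif item.startswith("artifacts="):
            artifacts = [c.strip() for c in item[10:].split(",") if c.strip()]
    if fs is None:
        raise ValidationError(f"{path}: missing '# fs=<Hz>' header line")
    if not lines:
        raise ValidationError(f"{path}: missing label line")
    labels = [c.strip() for c in lines.pop(0).split(",")]
    if len(lines) != len(labels):
        raise ValidationError(
            f"{path}: {len(labels)} labels but {len(lines)} sample rows"
        )
    samples = np.array([[float(v) for v in ln.split(",")] for ln in lines])
    return EpochRecording(labels, samples, fs, frozenset(artifacts))


def write_epoch(path: str | Path, epoch: EpochRecording) -> None:
    """Write an epoch in the delimited-matrix dialect read by ``read_epoch``."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={epoch.fs:g}\n")
        if epoch.artifact_channels:
            fh.write(f"# artifacts={','.join(sorted(epoch.artifact_channels))}\n")
        fh.write(",".join(epoch.channel_labels) + "\n")
        for row in epoch.samples:
            fh.write(",".join(f"{v:.10g}" for v in row) + "\n")


def read_annotations(path: str | Path, epoch: EpochRecording | None = None) -> AnnotationSet:
    """Parse the annotation JSON schema.

    Schema: ``{"events": [{"type", "t_start", "t_end", "channels"}],
    "soz": [...], "rbt": [...] | null, "outcome": "...|none"}``. When an
    epoch is supplied the channel sets are validated against its labels.
    """
    with open(path) as fh:
        doc = json.load(fh)
    events = [
        EventAnnotation(
            event_type=e["type"],
            t_start=float(e["t_start"]),
            t_end=float(e["t_end"]),
            channels=frozenset(e["channels"]),
        )
        for e in doc.get("events", [])
    ]
    rbt = doc.get("rbt")
    ann = AnnotationSet(
        events=events,
        soz=frozenset(doc.get("soz", [])),
        rbt=None if rbt is None else frozenset(rbt),
        outcome=doc.get("outcome", "none"),
    )
    if epoch is not None:
        ann.validate_against(epoch)
    return ann


def write_annotations(
    path: str | Path, annotations: AnnotationSet, core: frozenset[str] | None = None
) -> None:
    """Serialize an AnnotationSet (and optionally a detected core) to JSON."""
    doc: dict = {
        "events": [
            {
                "type": ev.event_type,
                "t_start": ev.t_start,
                "t_end": ev.t_end,
                "channels": sorted(ev.channels),
            }
            for ev in annotations.events
        ],
        "soz": sorted(annotations.soz),
        "rbt": None if annotations.rbt is None else sorted(annotations.rbt),
        "outcome": annotations.outcome,
    }
    if core is not None:
        doc["core"] = sorted(core)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# Signal conditioning

def rereference_median(epoch: EpochRecording) -> EpochRecording:
    """Re-reference every channel against the median of artifact-free channels.

    The per-sample median is computed over non-artifact channels only and
    subtracted from all channels (artifact rows included, so the container
    stays consistent, though they never enter analysis).
    """
    med = np.median(epoch.usable_samples(), axis=0)
    return replace(epoch, samples=epoch.samples - med[None, :])


def bandpass_filter(
    epoch: EpochRecording,
    low: float = 0.5,
    high: float = 150.0,
    order: int = 4,
    zero_phase: bool = True,
) -> EpochRecording:
    """Butterworth band-pass filter each channel.

    A fourth-order design, applied forward-backward by default so that
    transient event timing is not shifted (zero group delay; the effective
    attenuation order doubles). Set ``zero_phase=False`` for a single
    causal pass.
    """
    nyq = epoch.fs / 2
    if not 0 < low < high:
        raise ValidationError("need 0 < low < high")
    if high >= nyq:
        raise ValidationError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=epoch.fs, output="sos")
    if zero_phase:
        filtered = signal.sosfiltfilt(sos, epoch.samples, axis=1)
    else:
        filtered = signal.sosfilt(sos, epoch.samples, axis=1)
    return replace(epoch, samples=filtered)


def preprocess_epoch(
    epoch: EpochRecording, low: float = 0.5, high: float = 150.0
) -> EpochRecording:
    """Median re-reference, then band-pass filter (the standard chain)."""
    return bandpass_filter(rereference_median(epoch), low=low, high=high)
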