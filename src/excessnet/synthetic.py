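"""Synthetic multichannel epochs with planted coupling structure.

The generator emulates the structure of annotated preictal iEEG so every
pipeline stage is testable without recordings: dozens of channels of
band-limited (0.5–150 Hz) autoregressive background noise, a *linear
group* sharing a common Gaussian source at a configured Pearson
correlation (distractors the surrogate correction must ignore), and a
*planted core* whose pairs carry a purely non-linear dependence — for
each core pair one channel receives a private driver u linearly and the
other receives the standardized even function u² − E[u²], which has zero
Pearson correlation with u by symmetry yet substantial mutual
information. Transient epileptiform events of the four clinical types
(spike <70 ms, sharp wave 70–200 ms, slow wave, fast oscillation >30 Hz)
are injected additively at Poisson times, with affected channels
optionally enriched toward the SOZ/RBT.

Cohorts tie the planted structure to surgery outcomes: in the "aligned"
scenario favorable patients have core and SOZ inside the RBT while
unfavorable patients have the core disjoint from the RBT; "misaligned"
scrambles these relations for null calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .preprocess import (
    EVENT_TYPES,
    AnnotationSet,
    EpochRecording,
    EventAnnotation,
)

#: event duration bounds in seconds per type (spike <70 ms, sharp wave
#: 70–200 ms, slow wave 0.3–1 s, fast-oscillation burst 0.1–0.5 s)
EVENT_DURATION_BOUNDS = {
    "spike": (0.020, 0.069),
    "sharp_wave": (0.070, 0.200),
    "slow_wave": (0.300, 1.000),
    "fast_oscillation": (0.100, 0.500),
}

#: default event rates (events/min over the whole epoch), proportioned
#: like the clinical corpus (~38/35/22/5 % of ~60 events/min)
DEFAULT_EVENT_RATES = {
    "spike": 22.7,
    "slow_wave": 20.8,
    "sharp_wave": 13.4,
    "fast_oscillation": 3.1,
}


@dataclass
class SyntheticGroundTruth:
    """Planted structure of one synthetic epoch: the recovery reference."""

    channel_labels: list[str]
    planted_core: frozenset[str]
    linear_group: frozenset[str]
    soz: frozenset[str]
    rbt: frozenset[str] | None
    outcome: str
    coupling_strength: float = 1.0  # variance of each non-linear pair component
    linear_r: float = 0.7           # pairwise Pearson r inside the linear group
    seed: int = 0

    def __post_init__(self) -> None:
        labels = set(self.channel_labels)
        for name in ("planted_core", "linear_group", "soz"):
            s = frozenset(getattr(self, name))
            setattr(self, name, s)
            if not s <= labels:
                raise ValueError(f"{name} contains unknown channels")
        if self.rbt is not None:
            self.rbt = frozenset(self.rbt)
            if not self.rbt <= labels:
                raise ValueError("rbt contains unknown channels")


def default_labels(n_channels: int) -> list[str]:
    return [f"C{i:02d}" for i in range(1, n_channels + 1)]


def _ar2_background(rng: np.random.Generator, shape: tuple[int, ...], fs: float) -> np.ndarray:
    """Unit-variance AR(2) noise band-limited to 0.5–150 Hz.

    Poles at 0.8 and 0.6 give a red, EEG-like 1/f-ish spectrum before the
    band-pass; one second of burn-in is discarded.
    """
    burn = int(fs)
    white = rng.standard_normal(shape[:-1] + (shape[-1] + burn,))
    ar = sp_signal.lfilter([1.0], [1.0, -1.4, 0.48], white, axis=-1)[..., burn:]
    high = min(150.0, 0.45 * fs)
    sos = sp_signal.butter(4, [0.5, high], btype="bandpass", fs=fs, output="sos")
    x = sp_signal.sosfiltfilt(sos, ar, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def generate_epoch(
    n_channels: int = 50,
    duration: float = 180.0,
    fs: float = 512.0,
    truth: SyntheticGroundTruth | None = None,
) -> tuple[EpochRecording, SyntheticGroundTruth]:
    """Generate one epoch realizing the planted structure in ``truth``.

    All channels carry independent band-limited AR(2) background of unit
    variance. Linear-group channels additionally share a common Gaussian
    source mixed to pairwise correlation ``truth.linear_r``. Every pair
    (i, j), i < j, of the planted core gets a private band-limited driver
    u: channel i receives sqrt(SNR)·u and channel j receives
    sqrt(SNR)·(u² − E[u²])/sd — a dependence invisible to Pearson
    correlation. Channels are normalized to unit variance.
    """
    if duration < 16:
        raise ValueError("duration must be >= 16 s")
    if n_channels < 4:
        raise ValueError("need at least 4 channels")
    if truth is None:
        truth = SyntheticGroundTruth(
            channel_labels=default_labels(n_channels),
            planted_core=frozenset(), linear_group=frozenset(),
            soz=frozenset(), rbt=None, outcome="none",
        )
    labels = truth.channel_labels
    if len(labels) != n_channels:
        raise ValueError("truth labels do not match n_channels")
    rng = np.random.default_rng(np.random.SeedSequence(truth.seed))
    n = int(round(duration * fs))
    idx = {c: i for i, c in enumerate(labels)}

    samples = _ar2_background(rng, (n_channels, n), fs)

    lin = sorted(truth.linear_group)
    if len(lin) >= 2:
        common = _ar2_background(rng, (1, n), fs)[0]
        r = truth.linear_r
        for c in lin:
            i = idx[c]
            samples[i] = np.sqrt(r) * common + np.sqrt(1 - r) * samples[i]

    snr = truth.coupling_strength
    core = sorted(truth.planted_core)
    for a_pos, ca in enumerate(core):
        for cb in core[a_pos + 1:]:
            u = _ar2_background(rng, (1, n), fs)[0]
            samples[idx[ca]] += np.sqrt(snr) * _standardize(u)
            samples[idx[cb]] += np.sqrt(snr) * _standardize(u * u)

    samples /= samples.std(axis=-1, keepdims=True)
    epoch = EpochRecording(list(labels), samples, fs)
    return epoch, truth


def generate_events(
    truth: SyntheticGroundTruth,
    duration: float,
    rates: dict[str, float] | None = None,
    seed: int | np.random.SeedSequence | None = None,
    enrichment: float = 0.8,
    enrich_target: str = "soz",
    mean_extra_channels: float = 2.0,
) -> AnnotationSet:
    """Draw Poisson epileptiform events with type-specific durations.

    ``rates`` are events/min per type; event times are uniform, durations
    uniform within the type's bounds. Each event affects
    1 + Poisson(mean_extra_channels) channels, each drawn from the
    enrichment target set (soz/rbt/core) with probability ``enrichment``
    and uniformly otherwise. ``enrichment=1`` with a non-empty target set
    confines every event to that set.
    """
    rates = dict(DEFAULT_EVENT_RATES if rates is None else rates)
    rng = np.random.default_rng(seed)
    pool = list(truth.channel_labels)
    target_sets = {
        "soz": truth.soz, "rbt": truth.rbt or frozenset(),
        "core": truth.planted_core,
    }
    enriched = sorted(target_sets.get(enrich_target, frozenset())) or pool

    events: list[EventAnnotation] = []
    for etype in EVENT_TYPES:
        rate = rates.get(etype, 0.0)
        if rate < 0:
            raise ValueError("rates must be >= 0")
        n_ev = rng.poisson(rate * duration / 60.0)
        lo, hi = EVENT_DURATION_BOUNDS[etype]
        for _ in range(n_ev):
            d = rng.uniform(lo, hi)
            t0 = rng.uniform(0.0, duration - d)
            n_extra = rng.poisson(mean_extra_channels)
            chans = set()
            for _ in range(1 + n_extra):
                if rng.uniform() < enrichment:
                    chans.add(enriched[rng.integers(len(enriched))])
                else:
                    chans.add(pool[rng.integers(len(pool))])
            events.append(EventAnnotation(etype, t0, t0 + d, frozenset(chans)))
    events.sort(key=lambda e: (e.t_start, e.event_type))
    return AnnotationSet(events=events, soz=truth.soz, rbt=truth.rbt, outcome=truth.outcome)


def inject_events(
    epoch: EpochRecording,
    annotations: AnnotationSet,
    amplitude: float = 3.0,
    seed: int | np.random.SeedSequence | None = None,
) -> EpochRecording:
    """Additively inject event waveforms into the epoch (returns a copy).

    Spikes and sharp waves are biphasic transients (first derivative of a
    Gaussian), slow waves half-sine deflections, fast oscillations
    Hann-gated sinusoids of 35–120 Hz. ``amplitude`` scales the waveform
    relative to each channel's standard deviation.
    """
    rng = np.random.default_rng(seed)
    fs = epoch.fs
    samples = epoch.samples.copy()
    idx = {c: i for i, c in enumerate(epoch.channel_labels)}
    for ev in annotations.events:
        i0 = int(round(ev.t_start * fs))
        n = max(int(round(ev.duration * fs)), 4)
        n = min(n, samples.shape[1] - i0)
        t = np.linspace(-1.0, 1.0, n)
        if ev.event_type in ("spike", "sharp_wave"):
            wave = -t * np.exp(0.5 - 2 * t * t)  # biphasic, unit peak
        elif ev.event_type == "slow_wave":
            wave = np.sin(np.pi * (t + 1) / 2)
        else:  # fast oscillation: >30 Hz burst under a Hann window
            f = rng.uniform(35.0, 120.0)
            wave = np.hanning(n) * np.sin(2 * np.pi * f * np.arange(n) / fs)
        for c in ev.channels:
            row = idx[c]
            samples[row, i0:i0 + n] += amplitude * samples[row].std() * wave
    out = EpochRecording(
        list(epoch.channel_labels), samples, fs, epoch.artifact_channels
    )
    return out


def make_ground_truth(
    n_channels: int,
    outcome: str,
    scenario: str = "aligned",
    core_size: int = 4,
    linear_size: int = 4,
    soz_extra: int = 1,
    rbt_extra: int = 2,
    coupling_strength: float = 1.0,
    linear_r: float = 0.7,
    seed: int = 0,
) -> SyntheticGroundTruth:
    """Draw the channel-set structure of one synthetic patient.

    Aligned scenario: the SOZ covers the planted core plus ``soz_extra``
    neighbours; a favorable patient's RBT contains core and SOZ plus
    ``rbt_extra`` more channels, an unfavorable patient's RBT is disjoint
    from both; no-surgery patients have no RBT. The misaligned scenario
    draws the RBT independently of the planted structure.
    """
    if scenario not in ("aligned", "misaligned"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    labels = default_labels(n_channels)
    perm = [labels[i] for i in rng.permutation(n_channels)]
    core = frozenset(perm[:core_size])
    soz = frozenset(perm[:core_size + soz_extra])
    linear = frozenset(perm[core_size + soz_extra:core_size + soz_extra + linear_size])
    remaining = perm[core_size + soz_extra + linear_size:]

    rbt: frozenset[str] | None
    if outcome == "none":
        rbt = None
    elif scenario == "misaligned":
        rbt = frozenset(
            perm[i] for i in rng.choice(n_channels, size=core_size + rbt_extra, replace=False)
        )
    elif outcome == "favorable":
        rbt = soz | core | frozenset(remaining[:rbt_extra])
    else:  # unfavorable: resection missed the planted focus entirely
        rbt = frozenset(remaining[:core_size + rbt_extra])
    return SyntheticGroundTruth(
        channel_labels=labels,
        planted_core=core,
        linear_group=linear,
        soz=soz,
        rbt=rbt,
        outcome=outcome,
        coupling_strength=coupling_strength,
        linear_r=linear_r,
        seed=int(rng.integers(2**31)),
    )


def generate_cohort(
    n_favorable: int,
    n_unfavorable: int,
    n_nosurgery: int,
    scenario: str = "aligned",
    seed: int | None = 0,
    n_channels: int = 50,
    duration: float = 180.0,
    fs: float = 512.0,
    core_size: int = 4,
    linear_size: int = 4,
    coupling_strength: float = 1.0,
    linear_r: float = 0.7,
    event_rates: dict[str, float] | None = None,
    enrichment: float = 0.8,
    inject: bool = True,
) -> list[tuple[EpochRecording, AnnotationSet, SyntheticGroundTruth]]:
    """Generate a cohort of synthetic patients, one epoch each.

    Counts may each be zero. Identical seeds give byte-identical epochs
    and annotations.
    """
    ss = np.random.SeedSequence(seed)
    records = []
    outcomes = (
        ["favorable"] * n_favorable
        + ["unfavorable"] * n_unfavorable
        + ["none"] * n_nosurgery
    )
    children = ss.spawn(len(outcomes))
    for outcome, child in zip(outcomes, children):
        k1, k2, k3 = child.spawn(3)
        truth = make_ground_truth(
            n_channels, outcome, scenario=scenario,
            core_size=core_size, linear_size=linear_size,
            coupling_strength=coupling_strength, linear_r=linear_r,
            seed=int(k1.generate_state(1)[0] % 2**31),
        )
        epoch, truth = generate_epoch(n_channels, duration, fs, truth)
        ann = generate_events(
            truth, duration, rates=event_rates, seed=k2, enrichment=enrichment
        )
        if inject:
            epoch = inject_events(epoch, ann, seed=k3)
        records.append((epoch, ann, truth))
    return records
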