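"""Node strength and automatic core-channel detection.

The epoch-averaged excess matrix is collapsed to one number per channel —
the normalized node strength, i.e. the mean excess interrelation of that
channel with all others, confined to [0, 1]. The most strongly connected
channels (the "core") are then separated automatically: channels are
sorted by strength and the largest difference between adjacent values is
located on the linear and on the logarithmic scale; each scale proposes
the prefix above its largest gap. When the scales disagree the smaller
prefix wins — a conservative rule favouring precision over recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .interrelation import ExcessMatrix


@dataclass
class NodeStrengthVector:
    """Per-channel node strength in [0, 1], ordered like the labels."""

    strengths: np.ndarray
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.strengths = np.asarray(self.strengths, dtype=float)
        self.channel_labels = list(self.channel_labels)
        if self.strengths.shape != (len(self.channel_labels),):
            raise ValueError("strengths do not match labels")
        if self.strengths.min() < 0 or self.strengths.max() > 1:
            raise ValueError("strengths must lie in [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.channel_labels, self.strengths.tolist()))


@dataclass
class CoreSet:
    """The strength-sorted prefix of channels above the largest gap.

    ``split_index_linear`` / ``split_index_log`` are the prefix lengths
    each scale proposed (0 when the core is empty / the scale degenerate).
    """

    channels: frozenset[str]
    split_index_linear: int
    split_index_log: int
    ranked_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.channels = frozenset(self.channels)

    def __len__(self) -> int:
        return len(self.channels)


def node_strength(matrix: ExcessMatrix) -> NodeStrengthVector:
    """Mean off-diagonal excess interrelation per channel (row mean)."""
    if matrix.n < 2:
        raise ValueError("need at least 2 channels")
    strengths = matrix.values.sum(axis=1) / (matrix.n - 1)
    return NodeStrengthVector(strengths, matrix.channel_labels)


def detect_core(strengths: NodeStrengthVector, epsilon: float = 1e-6) -> CoreSet:
    """Largest-gap separation of the most strongly connected channels.

    Channels are sorted by descending strength (ties broken by label for
    determinism). Adjacent differences are scanned on the linear scale
    over all entries, and on the log scale over entries above ``epsilon``
    (zero-strength channels can never enter the core); each scale proposes
    the prefix above its largest gap, the first maximum winning on ties —
    so an all-equal profile degenerates to the single top channel. If both
    prefixes coincide that is the core; otherwise the smaller prefix is
    kept. No entry above ``epsilon`` means an empty core.
    """
    order = sorted(
        range(len(strengths.channel_labels)),
        key=lambda i: (-strengths.strengths[i], strengths.channel_labels[i]),
    )
    s = strengths.strengths[order]
    labels = [strengths.channel_labels[i] for i in order]
    n = len(s)
    if n < 2:
        raise ValueError("need at least 2 channels")

    m = int(np.sum(s > epsilon))  # entries eligible for the log scale
    if m == 0:
        return CoreSet(frozenset(), 0, 0, labels)

    lin_gaps = s[:-1] - s[1:]
    k_lin = int(np.argmax(lin_gaps)) + 1

    if m >= 2:
        log_gaps = np.diff(-np.log(s[:m]))
        k_log = int(np.argmax(log_gaps)) + 1
    else:
        k_log = 1  # a single positive entry: the log scale can only propose it

    k = k_lin if k_lin == k_log else min(k_lin, k_log)
    return CoreSet(frozenset(labels[:k]), k_lin, k_log, labels)
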