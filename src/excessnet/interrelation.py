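"""Windowed mutual information and surrogate-corrected excess matrices.

Pairwise mutual information (MI) is estimated on 8-s sliding windows
(1-s step) with an equiquantal (uniform-marginal) binning plug-in
estimator, normalized by log(n_bins) so that MI of any strictly monotone
deterministic relation is exactly 1. Because MI responds to linear and
non-linear dependence alike, each window's MI is contrasted against
multivariate IAAFT surrogates that conserve the linear structure: a pair's
*excess* value is MI_data − max(MI_surrogates) when the data exceed every
surrogate (a max-rank test at p <= 1/(n_surr+1)), else exactly zero.
Window matrices are averaged over the epoch; the similarity of each
segment matrix to that average is a Pearson correlation over the upper
triangle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .surrogates import multivariate_iaaft

EPOCH_AVERAGE = "epoch_average"

WINDOW_LENGTH = 8.0  # seconds
WINDOW_STEP = 1.0    # seconds


@dataclass
class ExcessMatrix:
    """Symmetric non-negative matrix of non-linear excess interrelation.

    ``window`` is the [t_start, t_end) interval in seconds, or the string
    ``"epoch_average"`` for an epoch-averaged matrix. Values live in
    [0, 1]; an element is zero unless the pair's MI significantly exceeded
    the linear-surrogate null.
    """

    values: np.ndarray
    channel_labels: list[str]
    window: tuple[float, float] | str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.channel_labels = list(self.channel_labels)
        n = len(self.channel_labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.channel_labels)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.channel_labels, columns=self.channel_labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, window: tuple[float, float] | str = EPOCH_AVERAGE) -> "ExcessMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), list(df.columns), window)


@dataclass
class WindowGrid:
    """The maximal set of 8-s windows at 1-s offsets starting at t=0."""

    windows: list[tuple[float, float]]
    window_length: float = WINDOW_LENGTH
    step: float = WINDOW_STEP

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)


def segment_windows(duration: float, fs: float) -> WindowGrid:
    """Sliding-window grid over an epoch of ``duration`` seconds.

    For an integer duration D >= 8 this yields floor(D − 8) + 1 windows;
    a trailing remainder shorter than 8 s is discarded.
    """
    if duration < WINDOW_LENGTH:
        raise ValueError(f"epoch of {duration:g} s is shorter than one {WINDOW_LENGTH:g}-s window")
    n_win = int(np.floor((duration - WINDOW_LENGTH) / WINDOW_STEP + 1e-9)) + 1
    windows = [(i * WINDOW_STEP, i * WINDOW_STEP + WINDOW_LENGTH) for i in range(n_win)]
    return WindowGrid(windows)


def window_slice(window: tuple[float, float], fs: float) -> slice:
    """Sample-index slice for a [t_start, t_end) window."""
    t0, t1 = window
    return slice(int(round(t0 * fs)), int(round(t1 * fs)))


# ---------------------------------------------------------------------------
# Mutual information

def _equiquantal_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-based bin index per sample along the last axis.

    Marginal bin counts are equal up to +-1 (exactly equal when the sample
    count divides by n_bins), making the marginals uniform and the
    log(n_bins) normalization tight.
    """
    order = np.argsort(x, axis=-1, kind="stable")
    ranks = np.empty(x.shape, dtype=np.int64)
    np.put_along_axis(ranks, order, np.broadcast_to(np.arange(x.shape[-1]), x.shape), axis=-1)
    return (ranks * n_bins) // x.shape[-1]


def _mi_from_bins(bx: np.ndarray, by: np.ndarray, n_bins: int) -> float:
    n = bx.shape[-1]
    joint = np.bincount(bx * n_bins + by, minlength=n_bins * n_bins).astype(float)
    joint = joint.reshape(n_bins, n_bins) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])))
    return mi / np.log(n_bins)


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int = 16) -> float:
    """Normalized plug-in mutual information of two signals, in [0, 1].

    Both signals are discretized into ``n_bins`` equiquantal bins;
    MI = sum p_ij log(p_ij / (p_i p_j)), normalized by log(n_bins) so any
    strictly monotone deterministic relation scores exactly 1.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    if x.size < n_bins * n_bins:
        raise ValueError(f"need at least n_bins^2 = {n_bins * n_bins} samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("signals must be finite")
    return _mi_from_bins(_equiquantal_bins(x, n_bins), _equiquantal_bins(y, n_bins), n_bins)


def mutual_information_from_joint(counts: np.ndarray) -> float:
    """Normalized MI of a discrete joint count table (diagnostic helper).

    Normalization uses log of the table's larger dimension.
    """
    counts = np.asarray(counts, dtype=float)
    p = counts / counts.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log(p[nz] / np.outer(px, py)[nz])))
    return mi / np.log(max(counts.shape))


# ---------------------------------------------------------------------------
# Excess interrelation

def excess_matrix(
    window_data: np.ndarray,
    channel_labels: list[str],
    n_surr: int = 19,
    n_bins: int = 16,
    seed: int | np.random.SeedSequence | None = None,
    max_iter: int = 100,
    window: tuple[float, float] | str = (0.0, WINDOW_LENGTH),
) -> ExcessMatrix:
    """Surrogate-corrected non-linear excess matrix of one window.

    For every channel pair, MI is computed on the data and on each of
    ``n_surr`` multivariate IAAFT surrogates; the matrix element is
    max(0, MI_data − max_k MI_surr_k) when MI_data strictly exceeds all
    surrogate values (one-sided max-rank test at p <= 1/(n_surr+1)), else
    exactly 0.
    """
    window_data = np.asarray(window_data, dtype=float)
    n_ch = window_data.shape[0]
    if n_ch < 2:
        raise ValueError("need at least 2 channels")
    if len(channel_labels) != n_ch:
        raise ValueError("labels do not match data")

    ens = multivariate_iaaft(window_data, n_surr=n_surr, max_iter=max_iter, seed=seed)
    # bin indices for data (index 0) and every surrogate, all channels at once
    stacked = np.concatenate([window_data[None], ens.surrogates], axis=0)
    bins = _equiquantal_bins(stacked, n_bins)

    values = np.zeros((n_ch, n_ch))
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            mi = np.array([
                _mi_from_bins(bins[k, i], bins[k, j], n_bins) for k in range(n_surr + 1)
            ])
            if mi[0] > mi[1:].max():
                values[i, j] = values[j, i] = mi[0] - mi[1:].max()
    return ExcessMatrix(values, channel_labels, window)


def epoch_average(matrices: list[ExcessMatrix]) -> ExcessMatrix:
    """Element-wise mean of window matrices, tagged ``epoch_average``."""
    if not matrices:
        raise ValueError("need at least one matrix")
    labels = matrices[0].channel_labels
    for m in matrices[1:]:
        if m.channel_labels != labels:
            raise ValueError("channel labels differ between matrices")
    mean = np.mean([m.values for m in matrices], axis=0)
    return ExcessMatrix(mean, labels, EPOCH_AVERAGE)


def matrix_similarity(segment_matrix: ExcessMatrix, average_matrix: ExcessMatrix) -> float:
    """Pearson correlation of the two matrices' upper-triangle elements.

    Returns NaN when either vector has zero variance (undefined
    correlation) — e.g. an all-zero segment matrix.
    """
    if segment_matrix.channel_labels != average_matrix.channel_labels:
        raise ValueError("channel labels differ")
    a = segment_matrix.upper_triangle()
    b = average_matrix.upper_triangle()
    if a.size < 3:
        raise ValueError("need at least 3 off-diagonal element pairs")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
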