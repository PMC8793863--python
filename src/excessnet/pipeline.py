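"""End-to-end epoch and cohort analysis drivers.

``analyze_epoch`` runs the full chain on one preprocessed epoch: sliding
8-s/1-s windows, surrogate-corrected excess matrix per window, epoch
average, node strengths, largest-gap core detection, and the
segment-vs-average similarity trace. ``run_cohort`` applies it to a
synthetic or recorded cohort and assembles the epoch-level channel-set
prediction table used by the outcome statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .interrelation import (
    EPOCH_AVERAGE,
    ExcessMatrix,
    epoch_average,
    excess_matrix,
    matrix_similarity,
    segment_windows,
    window_slice,
)
from .network import CoreSet, NodeStrengthVector, detect_core, node_strength
from .prediction import evaluate_pairings
from .preprocess import AnnotationSet, EpochRecording, preprocess_epoch, restrict_to_usable


@dataclass
class EpochAnalysis:
    """Everything the pipeline derives from one epoch."""

    window_matrices: list[ExcessMatrix]
    average: ExcessMatrix
    strengths: NodeStrengthVector
    core: CoreSet
    similarity: np.ndarray  # Pearson r of each window matrix vs the average


def analyze_epoch(
    epoch: EpochRecording,
    seed: int = 0,
    n_surr: int = 19,
    n_bins: int = 16,
    max_iter: int = 100,
    preprocess: bool = False,
) -> EpochAnalysis:
    """Run windowing, excess matrices, averaging and core detection.

    Artifact channels are excluded before matrix computation. Surrogate
    seeds are derived deterministically from ``seed`` and the window
    index, so identical seeds reproduce identical matrices byte for byte.
    Set ``preprocess=True`` to apply median re-referencing and band-pass
    filtering first (skip when the input is already conditioned).
    """
    if preprocess:
        epoch = preprocess_epoch(epoch)
    labels = epoch.usable_labels
    data = epoch.usable_samples()
    grid = segment_windows(epoch.duration, epoch.fs)
    matrices = []
    for w_index, window in enumerate(grid):
        sl = window_slice(window, epoch.fs)
        m = excess_matrix(
            data[:, sl],
            labels,
            n_surr=n_surr,
            n_bins=n_bins,
            seed=np.random.SeedSequence(entropy=seed, spawn_key=(w_index,)),
            max_iter=max_iter,
            window=window,
        )
        matrices.append(m)
    average = epoch_average(matrices)
    similarity = np.array([matrix_similarity(m, average) for m in matrices])
    strengths = node_strength(average)
    core = detect_core(strengths)
    return EpochAnalysis(matrices, average, strengths, core, similarity)


def run_cohort(
    records: list[tuple[EpochRecording, AnnotationSet, object]],
    seed: int = 0,
    n_surr: int = 19,
    n_bins: int = 16,
    max_iter: int = 100,
    preprocess: bool = False,
) -> tuple[pd.DataFrame, list[EpochAnalysis]]:
    """Analyze every epoch and build the pooled prediction table.

    Returns the epoch-level accuracy table (one block of pairing rows per
    epoch, with patient index and outcome attached) and the per-epoch
    analyses.
    """
    tables = []
    analyses = []
    for patient, (epoch, annotations, _truth) in enumerate(records):
        ann = restrict_to_usable(annotations, epoch)
        res = analyze_epoch(
            epoch, seed=seed + patient, n_surr=n_surr, n_bins=n_bins,
            max_iter=max_iter, preprocess=preprocess,
        )
        table = evaluate_pairings(ann, res.core, frozenset(epoch.usable_labels))
        table.insert(0, "patient", patient)
        table["outcome"] = ann.outcome
        tables.append(table)
        analyses.append(res)
    return pd.concat(tables, ignore_index=True), analyses
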