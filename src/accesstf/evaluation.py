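"""Scoring predictions against ChIP-seq-derived truth labels.

Motifs overlapping a ChIP-seq peak by at least one base are positives;
the rest are negatives.  ROC AUC is the rank statistic (probability a
random positive outranks a random negative, ties counted half) and PR
AUC is the area under the step precision-recall curve (no interpolation
between operating points), so both are comparable across tools.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .errors import UndefinedMetricError
from .genomic_io import GenomicInterval, interval_index

__all__ = [
    "label_by_peak_overlap",
    "roc_auc",
    "pr_auc",
    "posterior_bin_summary",
]


def label_by_peak_overlap(
    intervals: Sequence[GenomicInterval],
    peaks: Iterable[GenomicInterval],
    min_overlap: int = 1,
) -> np.ndarray:
    """Boolean labels: True iff the motif overlaps >= min_overlap bp of a peak."""
    trees = interval_index(peaks)
    labels = np.zeros(len(intervals), dtype=bool)
    for i, iv in enumerate(intervals):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            if min(iv.end, hit.end) - max(iv.start, hit.begin) >= min_overlap:
                labels[i] = True
                break
    return labels


def _check_labels(labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=bool)
    if labels.size == 0:
        raise UndefinedMetricError("no labelled scores")
    return labels


def roc_auc(scores, labels) -> float:
    """Rank-statistic ROC AUC; needs both classes present."""
    labels = _check_labels(labels)
    if labels.all() or not labels.any():
        raise UndefinedMetricError("ROC AUC undefined with a single class")
    return float(_skm.roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_auc(scores, labels) -> float:
    """Step-curve precision-recall AUC (average precision); needs positives."""
    labels = _check_labels(labels)
    if not labels.any():
        raise UndefinedMetricError("PR AUC undefined with no positives")
    return float(_skm.average_precision_score(labels, np.asarray(scores, dtype=float)))


def posterior_bin_summary(
    posteriors, signal, bin_edges: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
) -> pd.DataFrame:
    """Distribution of a binding signal within posterior-probability bins.

    Returns one row per bin with count and signal quartiles; empty bins
    are reported with count 0 and NaN quartiles.  Intended for plotting
    posterior calibration against ChIP read density around the motifs.
    """
    posteriors = np.asarray(posteriors, dtype=float)
    signal = np.asarray(signal, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    if edges[0] > 0 or edges[-1] < 1 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must increase and cover [0, 1]")
    which = np.clip(np.searchsorted(edges, posteriors, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        vals = signal[which == b]
        q = (
            np.percentile(vals, [25, 50, 75])
            if vals.size
            else np.array([np.nan] * 3)
        )
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "count": int(vals.size),
                "signal_q1": q[0],
                "signal_median": q[1],
                "signal_q3": q[2],
            }
        )
    return pd.DataFrame(rows)
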