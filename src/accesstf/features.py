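"""Per-motif input features for the binding model, and open-region classes.

Each candidate binding site carries four observables: motif match quality
``f`` (rescaled FIMO score), TSS proximity ``d`` (a 1/(1+dist/kb) squash),
evolutionary conservation ``c`` (mean per-base PhastCons-style score over
the motif), and local accessibility ``n`` (the smaller of the DNase tag
counts in the two flanking windows — taking the minimum penalises motifs
sitting at the edge of an accessible region).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CoordinateError
from .genomic_io import (
    ConservationTrack,
    GenomicInterval,
    TagTrack,
    TSSTable,
    interval_index,
)

__all__ = [
    "MotifSite",
    "REGION_CLASSES",
    "normalize_pwm_score",
    "normalize_tss_distance",
    "mean_conservation",
    "window_tag_count",
    "rpm_window_count",
    "extract_features",
    "classify_regions",
]


@dataclass
class MotifSite:
    """One genomic motif match with raw and normalized features."""

    interval: GenomicInterval
    pwm_id: str
    fimo_score: float
    tss_distance: int | None = None
    f: float | None = None
    d: float | None = None
    c: float | None = None
    n: int | None = None


def normalize_pwm_score(fimo_score: float) -> float:
    """Rescale a FIMO match score to [0, 1] as (score - 10) / 10, clamped.

    Scores of 10 and 20 map to 0 and 1; scores outside that span are
    clamped so the feature honours its declared range.
    """
    if not np.all(np.isfinite(fimo_score)):
        raise ValueError("non-finite FIMO score")
    return float(np.clip((fimo_score - 10.0) / 10.0, 0.0, 1.0))


def normalize_tss_distance(tss_distance: float) -> float:
    """Squash a TSS distance (bp) into (0, 1] as 1 / (1 + dist/1000)."""
    if tss_distance < 0:
        raise ValueError(f"negative TSS distance {tss_distance}")
    return 1.0 / (1.0 + tss_distance / 1000.0)


def mean_conservation(track: ConservationTrack, interval: GenomicInterval) -> float:
    """Mean per-base conservation over the motif; uncovered bases default."""
    return track.mean(interval.chrom, interval.start, interval.end)


def window_tag_count(track: TagTrack, interval: GenomicInterval, window: int = 200) -> int:
    """Min of the tag counts in the two flanking windows of size ``window``.

    Upstream window is [start - window, start), downstream [end, end + window),
    both on the reference strand (motif strand is ignored).  Windows running
    past the chromosome start are truncated at 0.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    left = track.count(interval.chrom, max(0, interval.start - window), interval.start)
    right = track.count(interval.chrom, interval.end, interval.end + window)
    return min(left, right)


def rpm_window_count(track: TagTrack, interval: GenomicInterval, window: int = 200) -> float:
    """Reads per million over both flanking windows combined."""
    if track.library_size <= 0:
        raise ValueError("empty tag library: RPM undefined")
    left = track.count(interval.chrom, max(0, interval.start - window), interval.start)
    right = track.count(interval.chrom, interval.end, interval.end + window)
    return (left + right) / track.library_size * 1e6


def extract_features(
    motifs: Sequence[MotifSite],
    tags: TagTrack,
    conservation: ConservationTrack,
    tss: TSSTable,
    window: int = 200,
) -> pd.DataFrame:
    """Fill in f, d, c, n for every motif and return a feature table.

    The TSS distance is measured from the motif midpoint to the nearest
    annotated TSS over all genes (expressed and not); motifs on
    chromosomes with no TSS raise, since ``d`` would be undefined.
    """
    rows = []
    for i, m in enumerate(motifs):
        near = tss.nearest(m.interval.chrom, m.interval.midpoint)
        if near is None:
            raise CoordinateError(
                f"no TSS on {m.interval.chrom}: TSS distance undefined for motif {i}"
            )
        m.tss_distance = near[0]
        m.f = normalize_pwm_score(m.fimo_score)
        m.d = normalize_tss_distance(m.tss_distance)
        m.c = mean_conservation(conservation, m.interval)
        m.n = window_tag_count(tags, m.interval, window=window)
        rows.append(
            {
                "motif_index": i,
                "pwm_id": m.pwm_id,
                "chrom": m.interval.chrom,
                "start": m.interval.start,
                "end": m.interval.end,
                "strand": m.interval.strand,
                "fimo_score": m.fimo_score,
                "tss_distance": m.tss_distance,
                "f": m.f,
                "d": m.d,
                "c": m.c,
                "n": m.n,
            }
        )
    return pd.DataFrame(rows)


REGION_CLASSES = (
    "active_promoter",
    "active_enhancer",
    "primed_enhancer",
    "heterochromatin_polycomb",
    "other",
)

# precedence order for histone-mark classification of open regions
_MARKS = ("H3K4me3", "H3K27ac", "H3K4me1", "H3K27me3", "H3K9me3")


def classify_regions(
    regions: Sequence[GenomicInterval],
    marks: Mapping[str, Iterable[GenomicInterval]],
) -> list[str]:
    """Assign each open region one chromatin-state category.

    Precedence: K27ac with K4me3 -> active promoter; K27ac alone ->
    active enhancer; K4me1 without either acetyl/K4me3 -> primed enhancer;
    K9me3 or K27me3 otherwise -> heterochromatin/polycomb; nothing -> other.
    Categories are mutually exclusive and exhaustive.
    """
    trees = {name: interval_index(ivs) for name, ivs in marks.items()}

    def hit(name: str, region: GenomicInterval) -> bool:
        tree = trees.get(name, {}).get(region.chrom)
        return bool(tree is not None and tree.overlap(region.start, region.end))

    classes = []
    for region in regions:
        k4me3 = hit("H3K4me3", region)
        k27ac = hit("H3K27ac", region)
        k4me1 = hit("H3K4me1", region)
        repressed = hit("H3K27me3", region) or hit("H3K9me3", region)
        if k27ac and k4me3:
            classes.append("active_promoter")
        elif k27ac:
            classes.append("active_enhancer")
        elif k4me1:
            classes.append("primed_enhancer")
        elif repressed:
            classes.append("heterochromatin_polycomb")
        else:
            classes.append("other")
    return classes
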