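"""Readers and writers for the text formats the toolkit consumes and emits.

All coordinates are 0-based half-open internally.  FIMO motif tables
(1-based, inclusive) are converted on read.  Writers emit deterministic
column and sort order so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import CoordinateError, ParseError, SchemaError

__all__ = [
    "GenomicInterval",
    "TagTrack",
    "ConservationTrack",
    "TSSTable",
    "read_motif_table",
    "write_motif_bed",
    "read_tag_bed",
    "write_tag_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_peaks",
    "write_peaks",
    "read_tss",
    "write_tss",
    "read_expression",
    "write_expression",
    "read_predictions",
    "write_predictions",
    "write_tfscores",
    "interval_index",
]

STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval, 0-based start (inclusive), end exclusive."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise CoordinateError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise CoordinateError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


class TagTrack:
    """Sequencing tag positions per chromosome.

    A tag is counted at a single base (its 5' position as written in the
    BED start field; tag strand is ignored for counting).  Positions are
    stored sorted with multiplicity, so counting tags in a window is a
    pair of binary searches.
    """

    def __init__(self, positions: Mapping[str, Iterable[int]] | None = None):
        self.positions: dict[str, np.ndarray] = {}
        if positions:
            for chrom, pos in positions.items():
                arr = np.sort(np.asarray(list(pos), dtype=np.int64))
                if arr.size and arr[0] < 0:
                    raise CoordinateError(f"negative tag position on {chrom}")
                self.positions[chrom] = arr
        self.library_size = int(sum(a.size for a in self.positions.values()))

    def count(self, chrom: str, start: int, end: int) -> int:
        """Number of tags with position in [start, end)."""
        arr = self.positions.get(chrom)
        if arr is None or start >= end:
            return 0
        lo = np.searchsorted(arr, start, side="left")
        hi = np.searchsorted(arr, end, side="left")
        return int(hi - lo)


class ConservationTrack:
    """Per-base conservation scores in [0, 1] over covered intervals.

    Uncovered bases take ``default`` (0 unless configured otherwise).
    Intervals on a chromosome must not overlap.
    """

    def __init__(
        self,
        intervals: Mapping[str, Iterable[tuple[int, int, float]]] | None = None,
        default: float = 0.0,
    ):
        self.default = float(default)
        self.intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if intervals:
            for chrom, rows in intervals.items():
                rows = sorted(rows)
                starts = np.array([r[0] for r in rows], dtype=np.int64)
                ends = np.array([r[1] for r in rows], dtype=np.int64)
                scores = np.array([r[2] for r in rows], dtype=float)
                if np.any(starts >= ends):
                    raise CoordinateError(f"empty conservation interval on {chrom}")
                if np.any(ends[:-1] > starts[1:]):
                    raise CoordinateError(f"overlapping conservation intervals on {chrom}")
                if np.any((scores < 0) | (scores > 1)):
                    raise ValueError("conservation scores must lie in [0, 1]")
                self.intervals[chrom] = (starts, ends, scores)

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Arithmetic mean of per-base scores over [start, end)."""
        if start >= end:
            raise CoordinateError("empty interval for conservation mean")
        length = end - start
        if chrom not in self.intervals:
            return self.default
        starts, ends, scores = self.intervals[chrom]
        total = 0.0
        covered = 0
        lo = np.searchsorted(ends, start, side="right")
        for i in range(lo, starts.size):
            if starts[i] >= end:
                break
            ov = min(end, ends[i]) - max(start, starts[i])
            if ov > 0:
                total += ov * scores[i]
                covered += ov
        total += (length - covered) * self.default
        return total / length


class TSSTable:
    """Transcription start sites with expressed-gene flags.

    Backed by a DataFrame with columns gene, chrom, tss, strand, expressed;
    (gene, tss) pairs are unique.  Nearest-TSS queries use binary search on
    per-chromosome sorted positions.
    """

    COLUMNS = ["gene", "chrom", "tss", "strand", "expressed"]

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise SchemaError(f"TSS table missing columns: {missing}")
        table = table[self.COLUMNS].copy()
        table["tss"] = table["tss"].astype(np.int64)
        table["expressed"] = table["expressed"].astype(bool)
        if table.duplicated(["gene", "tss"]).any():
            raise SchemaError("duplicate (gene, TSS) rows")
        self.table = table.sort_values(["chrom", "tss", "gene"]).reset_index(drop=True)
        self._index: dict[bool, dict[str, tuple[np.ndarray, np.ndarray]]] = {}

    def _chrom_index(self, expressed_only: bool):
        cache = self._index.setdefault(expressed_only, {})
        if not cache:
            tab = self.table[self.table["expressed"]] if expressed_only else self.table
            for chrom, sub in tab.groupby("chrom", sort=True):
                cache[chrom] = (
                    sub["tss"].to_numpy(),
                    sub["gene"].to_numpy(),
                )
        return cache

    def nearest(
        self, chrom: str, position: int, expressed_only: bool = False
    ) -> tuple[int, str] | None:
        """Distance and gene of the nearest TSS on ``chrom``, or None."""
        idx = self._chrom_index(expressed_only).get(chrom)
        if idx is None or idx[0].size == 0:
            return None
        tss, genes = idx
        i = int(np.searchsorted(tss, position))
        best = None
        for j in (i - 1, i):
            if 0 <= j < tss.size:
                d = abs(int(tss[j]) - position)
                if best is None or d < best[0]:
                    best = (d, str(genes[j]))
        return best


# ---------------------------------------------------------------------------
# readers / writers


def _read_lines(path) -> list[str]:
    with open(path) as fh:
        return fh.read().splitlines()


def read_motif_table(path, dialect: str = "fimo"):
    """Read a motif-match table into a list of :class:`MotifSite`.

    ``dialect='fimo'``: tab-separated with header columns motif_id,
    sequence_name, start, stop, strand, score; 1-based inclusive
    coordinates, converted to 0-based half-open on read.
    ``dialect='bed'``: BED6 (name=PWM id, score=match score), already
    0-based half-open.
    """
    from .features import MotifSite  # local import to avoid a cycle

    if dialect not in {"fimo", "bed"}:
        raise ValueError(f"unknown motif table dialect {dialect!r}")
    sites: list[MotifSite] = []
    lines = _read_lines(path)
    if dialect == "fimo":
        if not lines:
            raise ParseError(f"{path}: empty FIMO table")
        header = lines[0].split("\t")
        required = ["motif_id", "sequence_name", "start", "stop", "strand", "score"]
        try:
            cols = {name: header.index(name) for name in required}
        except ValueError as exc:
            raise SchemaError(f"{path}: FIMO header missing column ({exc})") from None
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                start1 = int(parts[cols["start"]])
                stop1 = int(parts[cols["stop"]])
                score = float(parts[cols["score"]])
                chrom = parts[cols["sequence_name"]]
                strand = parts[cols["strand"]]
                pwm = parts[cols["motif_id"]]
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed FIMO record ({exc})") from None
            start, end = start1 - 1, stop1
            if start < 0 or start >= end:
                raise CoordinateError(
                    f"{path}:{lineno}: bad coordinates {start1}..{stop1} after conversion"
                )
            sites.append(
                MotifSite(
                    interval=GenomicInterval(chrom, start, end, strand),
                    pwm_id=pwm,
                    fimo_score=score,
                )
            )
    else:
        for lineno, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                pwm = parts[3] if len(parts) > 3 else "."
                score = float(parts[4]) if len(parts) > 4 else 0.0
                strand = parts[5] if len(parts) > 5 else "."
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed BED record ({exc})") from None
            if start < 0 or start >= end:
                raise CoordinateError(f"{path}:{lineno}: bad interval {start}-{end}")
            sites.append(
                MotifSite(
                    interval=GenomicInterval(chrom, start, end, strand),
                    pwm_id=pwm,
                    fimo_score=score,
                )
            )
    return sites


def write_motif_bed(path, sites) -> None:
    """Write motif sites as BED6 (name=PWM id, score=FIMO score)."""
    rows = sorted(
        sites, key=lambda s: (s.interval.chrom, s.interval.start, s.interval.end, s.pwm_id)
    )
    with open(path, "w") as fh:
        for s in rows:
            iv = s.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.pwm_id}\t{s.fimo_score:.17g}\t{iv.strand}\n"
            )


def read_tag_bed(path) -> TagTrack:
    """Read sequencing tags from BED; each line is one tag at its start."""
    positions: dict[str, list[int]] = {}
    for lineno, line in enumerate(_read_lines(path), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        try:
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}:{lineno}: malformed tag BED record ({exc})") from None
        if start < 0 or start >= end:
            raise CoordinateError(f"{path}:{lineno}: bad interval {start}-{end}")
        positions.setdefault(chrom, []).append(start)
    return TagTrack(positions)


def write_tag_bed(path, track: TagTrack) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.positions):
            for pos in track.positions[chrom]:
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")


def read_bedgraph(path, default: float = 0.0) -> ConservationTrack:
    """Read a bedGraph into a conservation track; overlaps are an error."""
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, line in enumerate(_read_lines(path), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        try:
            chrom, start, end, score = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}:{lineno}: malformed bedGraph record ({exc})") from None
        intervals.setdefault(chrom, []).append((start, end, score))
    return ConservationTrack(intervals, default=default)


def write_bedgraph(path, track: ConservationTrack) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.intervals):
            starts, ends, scores = track.intervals[chrom]
            for s, e, v in zip(starts, ends, scores):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.17g}\n")


def read_peaks(path) -> list[GenomicInterval]:
    """Read a peak set from BED / narrowPeak (extra columns ignored)."""
    peaks = []
    for lineno, line in enumerate(_read_lines(path), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        try:
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}:{lineno}: malformed peak record ({exc})") from None
        if start < 0 or start >= end:
            raise CoordinateError(f"{path}:{lineno}: bad interval {start}-{end}")
        peaks.append(GenomicInterval(chrom, start, end))
    return sorted(peaks)


def write_peaks(path, peaks: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for p in sorted(peaks):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")


def read_tss(path) -> TSSTable:
    table = pd.read_csv(path, sep="\t")
    return TSSTable(table)


def write_tss(path, tss: TSSTable) -> None:
    out = tss.table.copy()
    out["expressed"] = out["expressed"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_expression(path):
    """Read an expression matrix TSV (see :class:`ExpressionMatrix`)."""
    from .expression import ExpressionMatrix

    table = pd.read_csv(path, sep="\t")
    return ExpressionMatrix.from_table(table)


def write_expression(path, matrix) -> None:
    matrix.to_table().to_csv(path, sep="\t", index=False)


PREDICTION_COLUMNS = ["motif_index", "pwm_id", "chrom", "start", "end", "y", "gamma", "call"]


def write_predictions(path, predictions: pd.DataFrame) -> None:
    """Write per-motif posterior records with a fixed column order."""
    missing = [c for c in PREDICTION_COLUMNS if c not in predictions.columns]
    if missing:
        raise SchemaError(f"prediction table missing columns: {missing}")
    out = predictions[PREDICTION_COLUMNS].copy()
    out["call"] = out["call"].astype(int)
    out = out.sort_values(["chrom", "start", "end", "pwm_id"]).reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_predictions(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in PREDICTION_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"prediction table missing columns: {missing}")
    table["call"] = table["call"].astype(bool)
    return table


TFSCORE_COLUMNS = ["pwm_id", "gene", "c1_6h", "c1_24h", "c2", "c3", "c4", "total", "rank"]


def write_tfscores(path, scores: pd.DataFrame) -> None:
    missing = [c for c in TFSCORE_COLUMNS if c not in scores.columns]
    if missing:
        raise SchemaError(f"TFScore table missing columns: {missing}")
    scores[TFSCORE_COLUMNS].to_csv(path, sep="\t", index=False)


def interval_index(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    """Build per-chromosome interval trees for overlap queries."""
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees
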