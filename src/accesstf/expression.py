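"""Time-course differential expression, permutation FDR and clustering.

The expression matrix carries two biological replicates per time point.
A gene is called differentially expressed (DE) when, at one or more
non-baseline time points, both replicate fold changes against the
baseline mean exceed the cutoff in the same direction — a deliberately
simple, replicate-consistent rule whose false discovery rate is
estimated by randomizing fold-change values across genes.  Selected
genes are standardized and grouped by K-means into a small number of
trajectory clusters whose coherence is summarized by the median
within-cluster Pearson correlation.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import ConfigurationError, SchemaError

__all__ = [
    "ExpressionMatrix",
    "DEResult",
    "PermutationFDR",
    "ClusterResult",
    "ConsistencyResult",
    "select_de_genes",
    "permutation_fdr",
    "cluster_de_genes",
    "call_upregulated_factors",
    "consistent_response_fraction",
]

_SAMPLE_RE = re.compile(r"^t(\d+(?:\.\d+)?)_rep(\d+)$")


class ExpressionMatrix:
    """Genes x (time point x replicate) abundance table with expressed flags.

    The TSV representation has columns ``gene``, ``expressed`` and one
    column per sample labelled ``t{hours}_rep{1,2}``.
    """

    def __init__(self, values: pd.DataFrame, expressed: pd.Series):
        if not isinstance(values.columns, pd.MultiIndex):
            raise SchemaError("values must have a (time, rep) column MultiIndex")
        counts = values.columns.to_frame(index=False).groupby("time")["rep"].count()
        if (counts != 2).any():
            raise SchemaError("each time point needs exactly 2 replicates")
        if (values.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        self.values = values.sort_index(axis=1)
        self.expressed = expressed.reindex(values.index).astype(bool)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def times(self) -> list[float]:
        return sorted(self.values.columns.get_level_values("time").unique())

    @property
    def baseline_time(self) -> float:
        return self.times[0]

    def replicate_means(self) -> pd.DataFrame:
        """Per-gene mean over replicates at each time point."""
        return self.values.T.groupby(level="time").mean().T

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "ExpressionMatrix":
        if "gene" not in table.columns:
            raise SchemaError("expression table needs a 'gene' column")
        table = table.set_index("gene")
        expressed = (
            table.pop("expressed").astype(bool)
            if "expressed" in table.columns
            else pd.Series(True, index=table.index)
        )
        cols = []
        for name in table.columns:
            m = _SAMPLE_RE.match(str(name))
            if not m:
                raise SchemaError(f"unrecognized sample column {name!r}")
            cols.append((float(m.group(1)), int(m.group(2))))
        table.columns = pd.MultiIndex.from_tuples(cols, names=["time", "rep"])
        return cls(table, expressed)

    def to_table(self) -> pd.DataFrame:
        out = self.values.copy()
        out.columns = [
            f"t{int(t) if float(t).is_integer() else t}_rep{r}" for t, r in out.columns
        ]
        out.insert(0, "expressed", self.expressed.astype(int))
        return out.reset_index(names="gene")


@dataclass
class DEResult:
    """Per-gene DE selection with the consistent fold-change statistic."""

    table: pd.DataFrame  # columns: max_fold, direction, selected
    fold_cutoff: float
    excluded: list[str] = field(default_factory=list)

    @property
    def selected_genes(self) -> pd.Index:
        return self.table.index[self.table["selected"]]


def _fold_change_frame(matrix: ExpressionMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Replicate fold changes vs the baseline replicate mean.

    Returns (fc, excluded) where fc has the non-baseline (time, rep)
    columns and excluded lists genes with zero baseline mean.
    """
    base = matrix.values[matrix.baseline_time].mean(axis=1)
    excluded = list(matrix.genes[base <= 0])
    keep = base > 0
    nonbase = matrix.values.loc[keep, matrix.values.columns.get_level_values("time") != matrix.baseline_time]
    fc = nonbase.div(base[keep], axis=0)
    return fc, excluded


def _consistent_calls(fc: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Per-gene up/down flags and max consistent fold from replicate FCs."""
    lo = fc.T.groupby(level="time").min().T  # per-time min over replicates
    hi = fc.T.groupby(level="time").max().T
    up = lo > cutoff
    down = hi < 1.0 / cutoff
    up_fold = lo.where(up).max(axis=1)
    down_fold = (1.0 / hi).where(down).max(axis=1)
    max_fold = up_fold.fillna(0.0).combine(down_fold.fillna(0.0), max)
    direction = pd.Series("none", index=fc.index)
    direction[down.any(axis=1)] = "down"
    direction[up.any(axis=1)] = "up"  # up wins ties for reporting
    return pd.DataFrame(
        {
            "max_fold": max_fold,
            "up": up.any(axis=1),
            "down": down.any(axis=1),
            "direction": direction,
        }
    )


def select_de_genes(matrix: ExpressionMatrix, fold_cutoff: float = 1.5) -> DEResult:
    """Replicate-consistent DE call: both replicate FCs beyond the cutoff
    in the same direction at >= 1 non-baseline time point (expressed genes
    only; zero-baseline genes are excluded with a warning)."""
    if fold_cutoff <= 1:
        raise ConfigurationError("fold cutoff must exceed 1")
    fc, excluded = _fold_change_frame(matrix)
    if excluded:
        warnings.warn(f"{len(excluded)} genes excluded for zero baseline", stacklevel=2)
    calls = _consistent_calls(fc, fold_cutoff)
    expressed = matrix.expressed.reindex(fc.index).fillna(False)
    table = pd.DataFrame(
        {
            "max_fold": calls["max_fold"],
            "direction": calls["direction"],
            "selected": (calls["up"] | calls["down"]) & expressed,
        }
    )
    table.loc[~table["selected"], "direction"] = "none"
    return DEResult(table=table, fold_cutoff=fold_cutoff, excluded=excluded)


@dataclass
class PermutationFDR:
    observed: int
    permuted_mean: float
    fdr: float  # NaN when no observed selections
    n_perm: int


def permutation_fdr(
    matrix: ExpressionMatrix,
    fold_cutoff: float = 1.5,
    n_perm: int = 100000,
    seed: int | None = None,
    chunk: int = 200,
) -> PermutationFDR:
    """FDR of the DE rule by randomizing fold changes across genes.

    Each permutation shuffles every fold-change column (time x replicate)
    independently across genes, re-applies the selection rule, and the FDR
    is the mean permuted selection count over the observed count.
    """
    fc, _ = _fold_change_frame(matrix)
    expressed = matrix.expressed.reindex(fc.index).fillna(False).to_numpy()
    times = fc.columns.get_level_values("time").to_numpy()
    F = fc.to_numpy(float)
    n_genes, n_cols = F.shape
    uniq_times = np.unique(times)
    tmask = [times == t for t in uniq_times]

    def count_selected(arr: np.ndarray) -> np.ndarray:
        # arr: (..., genes, cols); returns selected count per leading axis
        up_any = np.zeros(arr.shape[:-1], dtype=bool)
        down_any = np.zeros(arr.shape[:-1], dtype=bool)
        for mask in tmask:
            sub = arr[..., mask]
            up_any |= sub.min(axis=-1) > fold_cutoff
            down_any |= sub.max(axis=-1) < 1.0 / fold_cutoff
        sel = (up_any | down_any) & expressed
        return sel.sum(axis=-1)

    observed = int(count_selected(F))
    rng = np.random.default_rng(seed)
    permuted_counts = np.empty(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        block = np.empty((b, n_genes, n_cols))
        for j in range(n_cols):
            # independent permutation of column j for each of the b draws
            order = np.argsort(rng.random((b, n_genes)), axis=1)
            block[:, :, j] = F[:, j][order]
        permuted_counts[done : done + b] = count_selected(block)
        done += b
    pmean = float(permuted_counts.mean())
    fdr = pmean / observed if observed > 0 else float("nan")
    if observed == 0:
        warnings.warn("no observed selections: FDR undefined", stacklevel=2)
    return PermutationFDR(observed=observed, permuted_mean=pmean, fdr=fdr, n_perm=n_perm)


@dataclass
class ClusterResult:
    assignments: pd.Series  # gene -> cluster id (1..k)
    coherence: dict[int, float]  # median within-cluster pairwise Pearson r
    profiles: pd.DataFrame  # standardized per-time profiles used


def _standardize_profiles(matrix: ExpressionMatrix, genes: pd.Index) -> pd.DataFrame:
    prof = matrix.replicate_means().loc[genes]
    centered = prof.sub(prof.mean(axis=1), axis=0)
    sd = centered.std(axis=1, ddof=0)
    sd = sd.replace(0.0, 1.0)  # flat profiles stay at zero after centering
    return centered.div(sd, axis=0)


def cluster_de_genes(
    matrix: ExpressionMatrix,
    de: DEResult,
    k: int = 4,
    seed: int | None = None,
    n_init: int = 50,
) -> ClusterResult:
    """K-means on standardized DE-gene trajectories, with coherence report."""
    genes = de.selected_genes
    if len(genes) < k:
        raise ConfigurationError(f"only {len(genes)} DE genes; need >= k={k}")
    Z = _standardize_profiles(matrix, genes)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(Z.to_numpy())
    assignments = pd.Series(labels + 1, index=genes, name="cluster")
    coherence = {}
    for cid in range(1, k + 1):
        members = Z[assignments == cid]
        if len(members) < 2:
            coherence[cid] = float("nan")
            continue
        corr = np.corrcoef(members.to_numpy())
        iu = np.triu_indices(len(members), k=1)
        coherence[cid] = float(np.median(corr[iu]))
    return ClusterResult(assignments=assignments, coherence=coherence, profiles=Z)


def call_upregulated_factors(matrix: ExpressionMatrix, fold: float = 1.5) -> pd.Series:
    """Per-gene flag: consistently up-regulated beyond ``fold`` at >= 1 time."""
    fc, _ = _fold_change_frame(matrix)
    calls = _consistent_calls(fc, fold)
    expressed = matrix.expressed.reindex(fc.index).fillna(False)
    flags = (calls["up"] & expressed).reindex(matrix.genes).fillna(False)
    flags.name = "upregulated"
    return flags


@dataclass
class ConsistencyResult:
    observed_up: float
    observed_down: float
    null_up: np.ndarray
    null_down: np.ndarray

    def zscores(self) -> tuple[float, float]:
        zu = (self.observed_up - self.null_up.mean()) / max(self.null_up.std(), 1e-12)
        zd = (self.observed_down - self.null_down.mean()) / max(self.null_down.std(), 1e-12)
        return float(zu), float(zd)


def consistent_response_fraction(
    lfc: pd.DataFrame,
    threshold: float = 1.0,
    n_random: int = 1000,
    seed: int | None = None,
) -> ConsistencyResult:
    """Fraction of genes responding the same way in every knockdown.

    ``lfc`` is genes x conditions of log2 fold changes; a gene counts as
    commonly up (down) if its response exceeds +threshold (-threshold) in
    all conditions (default threshold log2(2), i.e. 2-fold).  The null
    background independently permutes each column across genes.
    """
    if lfc.shape[1] < 2:
        raise ConfigurationError("need >= 2 knockdown conditions")
    M = lfc.to_numpy(float)
    n_genes = M.shape[0]

    def fractions(arr):
        up = (arr > threshold).all(axis=-1).mean(axis=-1)
        down = (arr < -threshold).all(axis=-1).mean(axis=-1)
        return up, down

    obs_up, obs_down = fractions(M)
    rng = np.random.default_rng(seed)
    null_up = np.empty(n_random)
    null_down = np.empty(n_random)
    for i in range(n_random):
        perm = np.column_stack([rng.permutation(M[:, j]) for j in range(M.shape[1])])
        null_up[i], null_down[i] = fractions(perm)
    return ConsistencyResult(
        observed_up=float(obs_up),
        observed_down=float(obs_down),
        null_up=null_up,
        null_down=null_down,
    )
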