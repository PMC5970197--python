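"""TFScore: rank transcription factors by four integrated criteria.

For each PWM (one per TF family) the rubric combines:

1. gain of chromatin accessibility around its bound motifs at 6 h and
   24 h of the transition (summed per-motif RPM fold changes vs 0 h,
   binned to 0-5 points per time point);
2. enrichment of its bound motifs near differentially expressed gene
   clusters (one-sided Fisher exact test per cluster vs non-DE expressed
   genes; best -log10 P binned to 0-5 points);
3. +15 points if the factor itself is consistently up-regulated beyond
   1.5-fold during the transition;
4. relative expression within the factor family sharing the motif
   (+5 at the family maximum E down to -10 at or below E/6).

The final score is the sum, and factors are reported in descending rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .genomic_io import TSSTable

__all__ = [
    "ScoreRubric",
    "TFScoreRecord",
    "accessible_motifs",
    "criterion1_accessibility_gain",
    "assign_motifs_to_genes",
    "criterion2_cluster_enrichment",
    "criterion3_upregulation",
    "criterion4_family_expression",
    "total_tfscore",
    "score_factors",
]


@dataclass
class ScoreRubric:
    """Bin edges and increments of the four criteria, with defaults.

    A statistic maps to the number of edges strictly below it, so edges
    (600, 1000, ...) give +0 for <= 600, +1 for (600, 1000], and so on.
    The printed 24 h accessibility bins are internally inconsistent in the
    original description; the default here extends the 6 h structure from
    the first two 24 h bins (<=2000 -> +0, 2001-4000 -> +1) and is fully
    configurable.
    """

    c1_6h_edges: tuple[float, ...] = (600, 1000, 1500, 3000, 5000)
    c1_24h_edges: tuple[float, ...] = (2000, 4000, 6000, 9000, 15000)
    c2_edges: tuple[float, ...] = (8, 11, 14, 17, 20)
    c3_increment: int = 15
    c4_fractions: tuple[float, ...] = (1 / 6, 1 / 4, 1 / 2)  # of family max E
    c4_scores: tuple[int, ...] = (-10, -5, 0, 3, 5)  # <=E/6 .. ==E

    def __post_init__(self) -> None:
        for edges in (self.c1_6h_edges, self.c1_24h_edges, self.c2_edges, self.c4_fractions):
            if any(b <= a for a, b in zip(edges, edges[1:])):
                raise ConfigurationError("rubric bin edges must strictly increase")
        if len(self.c4_scores) != len(self.c4_fractions) + 2:
            raise ConfigurationError("criterion-4 needs one score per band")


def _bin_score(value: float, edges: Sequence[float]) -> int:
    return int(sum(value > e for e in edges))


@dataclass
class TFScoreRecord:
    pwm_id: str
    gene: str
    c1_6h: int
    c1_24h: int
    c2: int
    c3: int
    c4: int

    @property
    def total(self) -> int:
        return self.c1_6h + self.c1_24h + self.c2 + self.c3 + self.c4


def accessible_motifs(
    posteriors_by_time: Mapping[float, pd.DataFrame], threshold: float | None = None
) -> pd.DataFrame:
    """Union over time points of motifs whose hard call passes.

    Each table needs motif_index, pwm_id and either a boolean ``call``
    column (used when ``threshold`` is None) or a ``gamma`` column to
    threshold.  Returns the deduplicated accessible-motif table.
    """
    kept = []
    for t, tab in posteriors_by_time.items():
        mask = tab["call"].astype(bool) if threshold is None else tab["gamma"] >= threshold
        kept.append(tab.loc[mask, ["motif_index", "pwm_id", "chrom", "start", "end"]])
    if not kept:
        raise ConfigurationError("no posterior tables supplied")
    out = pd.concat(kept).drop_duplicates("motif_index")
    return out.sort_values("motif_index").reset_index(drop=True)


def criterion1_accessibility_gain(
    rpm: pd.DataFrame,
    rubric: ScoreRubric | None = None,
    pseudocount_rpm: float = 1.0,
) -> dict:
    """Accessibility-gain statistic and scores for one PWM.

    ``rpm`` has one row per accessible motif of the PWM with columns
    rpm_0h, rpm_6h, rpm_24h.  The statistic at time t is the sum over
    motifs of RPM_t / RPM_0; a zero baseline contributes RPM_t over a
    one-read-scale pseudocount so newly opened sites still count.
    """
    rubric = rubric or ScoreRubric()
    if len(rpm) == 0:
        return {"stat_6h": 0.0, "stat_24h": 0.0, "score_6h": 0, "score_24h": 0}
    base = rpm["rpm_0h"].to_numpy(float)
    base = np.where(base > 0, base, pseudocount_rpm)
    stat6 = float((rpm["rpm_6h"].to_numpy(float) / base).sum())
    stat24 = float((rpm["rpm_24h"].to_numpy(float) / base).sum())
    return {
        "stat_6h": stat6,
        "stat_24h": stat24,
        "score_6h": _bin_score(stat6, rubric.c1_6h_edges),
        "score_24h": _bin_score(stat24, rubric.c1_24h_edges),
    }


def assign_motifs_to_genes(
    motifs: pd.DataFrame,
    tss: TSSTable,
    max_distance: int = 100_000,
) -> pd.DataFrame:
    """Assign each accessible motif to its nearest expressed gene's TSS.

    Motifs farther than ``max_distance`` from every expressed TSS stay
    unassigned.  Returns rows (motif_index, pwm_id, gene, distance).
    """
    rows = []
    for _, m in motifs.iterrows():
        mid = (int(m["start"]) + int(m["end"])) // 2
        near = tss.nearest(m["chrom"], mid, expressed_only=True)
        if near is not None and near[0] <= max_distance:
            rows.append(
                {
                    "motif_index": m["motif_index"],
                    "pwm_id": m["pwm_id"],
                    "gene": near[1],
                    "distance": near[0],
                }
            )
    return pd.DataFrame(rows, columns=["motif_index", "pwm_id", "gene", "distance"])


def criterion2_cluster_enrichment(
    motif_genes: Iterable[str],
    clusters: Mapping[int, Iterable[str]],
    background_genes: Iterable[str],
    rubric: ScoreRubric | None = None,
) -> dict:
    """Best cluster-enrichment score for one PWM.

    For each DE cluster, a one-sided Fisher exact test compares the
    fraction of cluster genes carrying an assigned accessible motif with
    the non-DE expressed background.  The criterion score is the bin of
    the largest -log10 P across clusters.
    """
    rubric = rubric or ScoreRubric()
    motif_genes = set(motif_genes)
    background = set(background_genes)
    bg_pos = len(background & motif_genes)
    bg_neg = len(background) - bg_pos
    best = 0.0
    pvalues = {}
    for cid, genes in clusters.items():
        genes = set(genes)
        if not genes:
            continue
        a = len(genes & motif_genes)
        b = len(genes) - a
        _, p = stats.fisher_exact([[a, b], [bg_pos, bg_neg]], alternative="greater")
        pvalues[cid] = float(p)
        neglog = -np.log10(max(p, 1e-300))
        best = max(best, neglog)
    return {
        "best_neglog10_p": best,
        "score": _bin_score(best, rubric.c2_edges),
        "pvalues": pvalues,
    }


def criterion3_upregulation(
    gene: str, upregulated: pd.Series, rubric: ScoreRubric | None = None
) -> int:
    """+15 when the factor is consistently up-regulated, else 0."""
    rubric = rubric or ScoreRubric()
    if gene not in upregulated.index:
        warnings.warn(f"factor {gene!r} absent from expression matrix", stacklevel=2)
        return 0
    return rubric.c3_increment if bool(upregulated[gene]) else 0


def criterion4_family_expression(
    member_expression: Mapping[str, float], rubric: ScoreRubric | None = None
) -> dict[str, int]:
    """Score each family member by its expression relative to the max E.

    +5 at E; +3 in (E/2, E); +0 in (E/4, E/2]; -5 in (E/6, E/4];
    -10 at or below E/6.  An all-zero family gets -10 throughout.
    """
    rubric = rubric or ScoreRubric()
    if not member_expression:
        raise ConfigurationError("empty factor family")
    E = max(member_expression.values())
    lo, mid, hi = rubric.c4_scores[0], rubric.c4_scores[1:-1], rubric.c4_scores[-1]
    if E <= 0:
        warnings.warn("all-zero factor family expression", stacklevel=2)
        return {g: lo for g in member_expression}
    scores = {}
    for g, x in member_expression.items():
        if np.isclose(x, E):
            scores[g] = hi
        else:
            band = sum(x > frac * E for frac in rubric.c4_fractions)
            scores[g] = ([lo] + list(mid))[band]
    return scores


def total_tfscore(records: Iterable[TFScoreRecord]) -> pd.DataFrame:
    """Ranked table: total = sum of components, ties broken by gene name."""
    rows = [
        {
            "pwm_id": r.pwm_id,
            "gene": r.gene,
            "c1_6h": r.c1_6h,
            "c1_24h": r.c1_24h,
            "c2": r.c2,
            "c3": r.c3,
            "c4": r.c4,
            "total": r.total,
        }
        for r in records
    ]
    out = pd.DataFrame(
        rows, columns=["pwm_id", "gene", "c1_6h", "c1_24h", "c2", "c3", "c4", "total"]
    )
    out = out.sort_values(["total", "gene"], ascending=[False, True]).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def score_factors(
    accessible: pd.DataFrame,
    rpm_by_pwm: Mapping[str, pd.DataFrame],
    tss: TSSTable,
    clusters: Mapping[int, Iterable[str]],
    background_genes: Iterable[str],
    upregulated: pd.Series,
    family_table: pd.DataFrame,
    expression_level: pd.Series,
    rubric: ScoreRubric | None = None,
    max_distance: int = 100_000,
) -> tuple[pd.DataFrame, dict]:
    """Run the full rubric for every (PWM, member factor) pair.

    ``family_table`` has columns pwm_id, gene, family; ``expression_level``
    is the per-gene level used for the within-family comparison (e.g. the
    mean abundance over the time course).  Returns the ranked score table
    and an audit dict of intermediate statistics.
    """
    rubric = rubric or ScoreRubric()
    assignments = assign_motifs_to_genes(accessible, tss, max_distance=max_distance)
    audit: dict = {"criterion1": {}, "criterion2": {}}
    records = []
    for pwm_id, members in family_table.groupby("pwm_id"):
        c1 = criterion1_accessibility_gain(
            rpm_by_pwm.get(pwm_id, pd.DataFrame(columns=["rpm_0h", "rpm_6h", "rpm_24h"])),
            rubric,
        )
        genes_with_motif = (
            assignments.loc[assignments["pwm_id"] == pwm_id, "gene"].unique().tolist()
        )
        c2 = criterion2_cluster_enrichment(genes_with_motif, clusters, background_genes, rubric)
        audit["criterion1"][pwm_id] = {k: c1[k] for k in ("stat_6h", "stat_24h")}
        audit["criterion2"][pwm_id] = {
            "best_neglog10_p": c2["best_neglog10_p"],
            "pvalues": c2["pvalues"],
        }
        fam_expr = {
            g: float(expression_level.get(g, 0.0)) for g in members["gene"]
        }
        c4_scores = criterion4_family_expression(fam_expr, rubric)
        for gene in members["gene"]:
            records.append(
                TFScoreRecord(
                    pwm_id=pwm_id,
                    gene=gene,
                    c1_6h=c1["score_6h"],
                    c1_24h=c1["score_24h"],
                    c2=c2["score"],
                    c3=criterion3_upregulation(gene, upregulated, rubric),
                    c4=c4_scores[gene],
                )
            )
    return total_tfscore(records), audit
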