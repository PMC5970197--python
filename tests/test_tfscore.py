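import math

import numpy as np
import pandas as pd
import pytest

import accesstf as a
from accesstf import tfscore as tf
from accesstf.errors import ConfigurationError
from accesstf.genomic_io import TSSTable


@pytest.fixture
def rubric():
    return tf.ScoreRubric()


class TestCriterion1:
    @pytest.mark.parametrize(
        "stat,score",
        [(0.0, 0), (600.0, 0), (800.0, 1), (1000.0, 1), (1200.0, 2), (2000.0, 3),
         (4000.0, 4), (5002.0, 5)],
    )
    def test_6h_bins(self, rubric, stat, score):
        # one motif whose 6 h fold change equals the target statistic
        rpm = pd.DataFrame({"rpm_0h": [1.0], "rpm_6h": [stat], "rpm_24h": [0.0]})
        out = tf.criterion1_accessibility_gain(rpm, rubric)
        assert out["stat_6h"] == pytest.approx(stat)
        assert out["score_6h"] == score

    @pytest.mark.parametrize(
        "stat,score", [(1500.0, 0), (2500.0, 1), (5000.0, 2), (8000.0, 3), (12000.0, 4), (20000.0, 5)]
    )
    def test_24h_bins(self, rubric, stat, score):
        rpm = pd.DataFrame({"rpm_0h": [1.0], "rpm_6h": [0.0], "rpm_24h": [stat]})
        assert tf.criterion1_accessibility_gain(rpm, rubric)["score_24h"] == score

    def test_statistic_sums_over_motifs(self, rubric):
        rpm = pd.DataFrame(
            {"rpm_0h": [2.0, 4.0], "rpm_6h": [800.0, 1200.0], "rpm_24h": [0.0, 0.0]}
        )
        out = tf.criterion1_accessibility_gain(rpm, rubric)
        assert out["stat_6h"] == pytest.approx(800 / 2 + 1200 / 4)

    def test_zero_baseline_uses_pseudocount(self, rubric):
        rpm = pd.DataFrame({"rpm_0h": [0.0], "rpm_6h": [700.0], "rpm_24h": [0.0]})
        out = tf.criterion1_accessibility_gain(rpm, rubric, pseudocount_rpm=1.0)
        assert out["stat_6h"] == pytest.approx(700.0)

    def test_no_accessible_motifs_scores_zero(self, rubric):
        out = tf.criterion1_accessibility_gain(
            pd.DataFrame(columns=["rpm_0h", "rpm_6h", "rpm_24h"]), rubric
        )
        assert out == {"stat_6h": 0.0, "stat_24h": 0.0, "score_6h": 0, "score_24h": 0}

    def test_monotone_in_statistic(self, rubric):
        scores = [
            tf.criterion1_accessibility_gain(
                pd.DataFrame({"rpm_0h": [1.0], "rpm_6h": [s], "rpm_24h": [0.0]}), rubric
            )["score_6h"]
            for s in np.linspace(0, 7000, 40)
        ]
        assert all(b >= a for a, b in zip(scores, scores[1:]))


class TestMotifGeneAssignment:
    def make_tss(self):
        return TSSTable(
            pd.DataFrame(
                {
                    "gene": ["A", "B", "C"],
                    "chrom": ["chr1"] * 3,
                    "tss": [10_000, 340_000, 400_000],
                    "strand": ["+", "-", "+"],
                    "expressed": [True, True, False],
                }
            )
        )

    def test_within_distance_assigned_to_nearest_expressed(self):
        motifs = pd.DataFrame(
            {
                "motif_index": [0, 1, 2],
                "pwm_id": ["P1"] * 3,
                "chrom": ["chr1"] * 3,
                "start": [15_000, 395_000, 800_000],
                "end": [15_010, 395_010, 800_010],
            }
        )
        out = tf.assign_motifs_to_genes(motifs, self.make_tss(), max_distance=100_000)
        # motif 0 -> A (5 kb); motif 1 -> B (55 kb; C is closer at 5 kb but
        # not expressed); motif 2 unassigned (> 100 kb from expressed genes)
        assert out.set_index("motif_index")["gene"].to_dict() == {0: "A", 1: "B"}

    def test_matches_brute_force_on_fixture(self, fixture_dir):
        truth = fixture_dir["truth"].iloc[:200]
        from accesstf import genomic_io as gio

        tss = gio.read_tss(fixture_dir["dir"] / "tss.tsv")
        out = tf.assign_motifs_to_genes(truth, tss, max_distance=100_000)
        tab = tss.table[tss.table["expressed"]]
        for row in out.itertuples():
            mid = (
                int(truth.loc[truth["motif_index"] == row.motif_index, "start"].iloc[0])
                + int(truth.loc[truth["motif_index"] == row.motif_index, "end"].iloc[0])
            ) // 2
            dists = (tab["tss"] - mid).abs()
            assert row.distance == dists.min()


def hypergeom_tail_enumeration(a_, b_, c_, d_):
    """P(X >= a) for the 2x2 margins, by direct binomial-coefficient sums."""
    M, K, n = a_ + b_ + c_ + d_, a_ + c_, a_ + b_
    total = 0.0
    for x in range(a_, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(M - K, n - x) / math.comb(M, n)
    return total


class TestCriterion2:
    @pytest.mark.parametrize("neglogp,score", [(3.0, 0), (8.0, 0), (9.0, 1), (12.0, 2), (15.0, 3), (18.0, 4), (25.0, 5)])
    def test_bins(self, rubric, neglogp, score):
        assert tf._bin_score(neglogp, rubric.c2_edges) == score

    def test_exact_test_matches_hypergeometric_enumeration(self, rubric):
        # 20-gene toy: cluster of 8 (5 with motif), background of 12 (2 with)
        cluster = [f"C{i}" for i in range(8)]
        background = [f"B{i}" for i in range(12)]
        motif_genes = cluster[:5] + background[:2]
        out = tf.criterion2_cluster_enrichment(motif_genes, {1: cluster}, background, rubric)
        expected = hypergeom_tail_enumeration(5, 3, 2, 10)
        assert out["pvalues"][1] == pytest.approx(expected, abs=1e-12)

    def test_best_cluster_drives_score(self, rubric):
        background = [f"B{i}" for i in range(1000)]
        strong = [f"S{i}" for i in range(30)]
        weak = [f"W{i}" for i in range(30)]
        motif_genes = strong[:15] + background[:40]
        out = tf.criterion2_cluster_enrichment(
            motif_genes, {1: weak, 2: strong}, background, rubric
        )
        assert out["score"] == 2  # -log10 p ~ 12 for the strong cluster
        assert out["pvalues"][2] < out["pvalues"][1]

    def test_empty_cluster_skipped(self, rubric):
        out = tf.criterion2_cluster_enrichment(["A"], {1: []}, ["A", "B"], rubric)
        assert out["score"] == 0 and out["pvalues"] == {}


class TestCriterion3:
    def test_flag_rules(self, rubric):
        up = pd.Series({"STAT3": True, "ATF2": False})
        assert tf.criterion3_upregulation("STAT3", up, rubric) == 15
        assert tf.criterion3_upregulation("ATF2", up, rubric) == 0

    def test_absent_factor_warns_and_scores_zero(self, rubric):
        with pytest.warns(UserWarning):
            assert tf.criterion3_upregulation("NOPE", pd.Series(dtype=bool), rubric) == 0


class TestCriterion4:
    def test_band_scores(self, rubric):
        family = {"A": 100.0, "B": 60.0, "C": 40.0, "D": 20.0, "E": 10.0}
        out = tf.criterion4_family_expression(family, rubric)
        assert out == {"A": 5, "B": 3, "C": 0, "D": -5, "E": -10}

    def test_member_at_one_eighth_of_max(self, rubric):
        out = tf.criterion4_family_expression({"A": 80.0, "B": 10.0}, rubric)
        assert out["B"] == -10

    def test_all_zero_family(self, rubric):
        with pytest.warns(UserWarning):
            out = tf.criterion4_family_expression({"A": 0.0, "B": 0.0}, rubric)
        assert out == {"A": -10, "B": -10}

    def test_empty_family_rejected(self, rubric):
        with pytest.raises(ConfigurationError):
            tf.criterion4_family_expression({}, rubric)


class TestTotal:
    def test_sum_rank_and_tiebreak(self):
        records = [
            tf.TFScoreRecord("P1", "ZEB1", 3, 4, 2, 15, 5),
            tf.TFScoreRecord("P2", "ATF3", 0, 0, 0, 0, 0),
            tf.TFScoreRecord("P3", "ABL1", 3, 4, 2, 15, 5),
        ]
        out = tf.total_tfscore(records)
        assert out.loc[0, "total"] == 29 and out.loc[0, "gene"] == "ABL1"
        assert out.loc[1, "gene"] == "ZEB1"  # tie broken alphabetically
        assert out["rank"].tolist() == [1, 2, 3]
        # permuting input order leaves the ranking unchanged
        out2 = tf.total_tfscore(records[::-1])
        pd.testing.assert_frame_equal(out, out2)

    def test_component_ranges(self, rubric):
        assert {tf._bin_score(v, rubric.c1_6h_edges) for v in np.linspace(0, 10**5, 500)} <= set(range(6))
        assert set(
            tf.criterion4_family_expression(
                {f"G{i}": float(x) for i, x in enumerate(np.linspace(0.01, 100, 50))}, rubric
            ).values()
        ) <= {-10, -5, 0, 3, 5}


class TestAccessibleMotifs:
    def test_union_over_time_points(self):
        def table(idx, call):
            return pd.DataFrame(
                {
                    "motif_index": idx,
                    "pwm_id": ["P1"] * len(idx),
                    "chrom": ["chr1"] * len(idx),
                    "start": [10 * i for i in idx],
                    "end": [10 * i + 5 for i in idx],
                    "gamma": [1.0 if c else 0.0 for c in call],
                    "call": call,
                }
            )

        posts = {0.0: table([0, 1, 2], [True, False, False]),
                 6.0: table([0, 1, 2], [False, True, False])}
        out = tf.accessible_motifs(posts)
        assert out["motif_index"].tolist() == [0, 1]


def test_engineered_pwm_ranks_first():
    """A PWM built to gain accessibility, sit near up-regulated cluster
    genes, and have its factor up-regulated must outrank neutral PWMs."""
    rng = np.random.default_rng(13)
    genes = [f"G{i:03d}" for i in range(120)]
    tss = TSSTable(
        pd.DataFrame(
            {
                "gene": genes,
                "chrom": "chr1",
                "tss": 100_000 * (1 + np.arange(120)),
                "strand": "+",
                "expressed": True,
            }
        )
    )
    cluster_genes = genes[:30]
    background = genes[30:]
    # winner motifs near the cluster genes, loser motifs near background genes
    def motif_frame(pwm, gene_slice, offset):
        rows = []
        for i, g in enumerate(gene_slice):
            pos = 100_000 * (genes.index(g) + 1) + offset
            rows.append(
                {"motif_index": len(rows) + (0 if pwm == "P_win" else 1000),
                 "pwm_id": pwm, "chrom": "chr1", "start": pos, "end": pos + 10}
            )
        return pd.DataFrame(rows)

    win_motifs = motif_frame("P_win", cluster_genes[:20], 500)
    lose_motifs = motif_frame("P_lose", background[:20], 700)
    accessible = pd.concat([win_motifs, lose_motifs], ignore_index=True)
    rpm_by_pwm = {
        "P_win": pd.DataFrame(
            {"rpm_0h": np.ones(20), "rpm_6h": np.full(20, 60.0), "rpm_24h": np.full(20, 160.0)}
        ),
        "P_lose": pd.DataFrame(
            {"rpm_0h": np.ones(20), "rpm_6h": np.ones(20), "rpm_24h": np.ones(20)}
        ),
    }
    upregulated = pd.Series(False, index=genes + ["TF_WIN", "TF_LOSE"])
    upregulated["TF_WIN"] = True
    family_table = pd.DataFrame(
        {"pwm_id": ["P_win", "P_lose"], "gene": ["TF_WIN", "TF_LOSE"], "family": ["fw", "fl"]}
    )
    level = pd.Series(100.0, index=["TF_WIN", "TF_LOSE"])
    scores, audit = tf.score_factors(
        accessible, rpm_by_pwm, tss, {1: cluster_genes}, background,
        upregulated, family_table, level,
    )
    assert scores.loc[0, "pwm_id"] == "P_win"
    assert scores.loc[0, "total"] > scores.loc[1, "total"]
    assert scores.loc[0, "c3"] == 15 and scores.loc[0, "c1_6h"] >= 1
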