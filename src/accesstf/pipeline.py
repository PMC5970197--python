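"""End-to-end orchestration: simulate -> features -> fit -> predict ->
evaluate -> DE/cluster -> TF ranking, with plain-file handoff between
stages and a checksummed manifest for provenance.

Each stage reads its inputs from files written by the previous stage and
writes its own artifact, so any suffix of the pipeline can be re-run in
isolation.  All randomness flows from the single seed in the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, expression, features, genomic_io, model, tfscore
from .errors import ConfigurationError
from .synthetic_data import SimulationScenario, simulate_expression_timecourse, simulate_genome_fixture

__all__ = ["RunConfig", "STAGES", "run_full"]

log = logging.getLogger("accesstf")

STAGES = ("simulate", "features", "fit", "predict", "evaluate", "de", "tfscore")


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    scenario: SimulationScenario | None = None
    tol: float = 1e-6
    max_iter: int = 500
    call_threshold: float = model.DEFAULT_CALL_THRESHOLD
    n_train: int = 10000
    n_test: int = 10000
    fold_cutoff: float = 1.5
    n_perm: int = 1000
    k_clusters: int = 4
    max_motif_gene_distance: int = 100_000
    rubric: tfscore.ScoreRubric = field(default_factory=tfscore.ScoreRubric)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        scenario = raw.pop("scenario", None)
        rubric = raw.pop("rubric", None)
        cfg = cls(**raw)
        if scenario is not None:
            from .model import ModelParams

            if "true_params" in scenario:
                scenario["true_params"] = ModelParams.from_dict(scenario["true_params"])
            for key in ("c_beta", "fold_change_range", "accessibility_gain"):
                if key in scenario:
                    scenario[key] = tuple(scenario[key])
            cfg.scenario = SimulationScenario(**scenario)
        if rubric is not None:
            for key in ("c1_6h_edges", "c1_24h_edges", "c2_edges", "c4_fractions", "c4_scores"):
                if key in rubric:
                    rubric[key] = tuple(rubric[key])
            cfg.rubric = tfscore.ScoreRubric(**rubric)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_simulate(cfg: RunConfig, out: Path) -> None:
    scenario = cfg.scenario or SimulationScenario(seed=cfg.seed)
    simulate_genome_fixture(scenario, out)
    matrix, labels = simulate_expression_timecourse(scenario)
    genomic_io.write_expression(out / "expression.tsv", matrix)
    labels.reset_index(names="gene").to_csv(out / "expression_truth.tsv", sep="\t", index=False)
    scenario.to_json(out / "scenario.json")


def _stage_features(cfg: RunConfig, out: Path) -> None:
    motifs = genomic_io.read_motif_table(out / "motifs.bed", dialect="bed")
    cons = genomic_io.read_bedgraph(out / "conservation.bedgraph")
    tss = genomic_io.read_tss(out / "tss.tsv")
    for label in ("0h", "6h", "24h"):
        tags = genomic_io.read_tag_bed(out / f"tags_{label}.bed")
        feats = features.extract_features(motifs, tags, cons, tss)
        rpm = [
            features.rpm_window_count(tags, m.interval) for m in motifs
        ]
        feats["rpm"] = rpm
        feats.to_csv(out / f"features_{label}.tsv", sep="\t", index=False, float_format="%.10g")


def _stage_fit(cfg: RunConfig, out: Path) -> None:
    feats = pd.read_csv(out / "features_0h.tsv", sep="\t")
    train, test = model.split_train_test(feats, cfg.n_train, cfg.n_test, seed=cfg.seed)
    params, report = model.fit_em(train, tol=cfg.tol, max_iter=cfg.max_iter, seed=cfg.seed)
    (out / "params.json").write_text(json.dumps(params.to_dict(), indent=2, sort_keys=True))
    (out / "fit_report.json").write_text(
        json.dumps(
            {
                "iterations": report.iterations,
                "loglik": report.loglik,
                "converged": report.converged,
                "seed": cfg.seed,
            },
            indent=2,
        )
    )
    train.to_csv(out / "train.tsv", sep="\t", index=False, float_format="%.10g")
    test.to_csv(out / "test.tsv", sep="\t", index=False, float_format="%.10g")


def _stage_predict(cfg: RunConfig, out: Path) -> None:
    params = model.ModelParams.from_dict(json.loads((out / "params.json").read_text()))
    for label in ("0h", "6h", "24h"):
        feats = pd.read_csv(out / f"features_{label}.tsv", sep="\t")
        pred = model.predict(params, feats, threshold=cfg.call_threshold)
        genomic_io.write_predictions(out / f"posteriors_{label}.tsv", pred)
    test = pd.read_csv(out / "test.tsv", sep="\t")
    pred = model.predict(params, test, threshold=cfg.call_threshold)
    genomic_io.write_predictions(out / "posteriors_test.tsv", pred)


def _stage_evaluate(cfg: RunConfig, out: Path) -> None:
    pred = genomic_io.read_predictions(out / "posteriors_test.tsv")
    peaks = genomic_io.read_peaks(out / "peaks.bed")
    intervals = [
        genomic_io.GenomicInterval(r.chrom, int(r.start), int(r.end))
        for r in pred.itertuples()
    ]
    labels = evaluation.label_by_peak_overlap(intervals, peaks)
    metrics = {
        "roc_auc": evaluation.roc_auc(pred["gamma"], labels),
        "pr_auc": evaluation.pr_auc(pred["gamma"], labels),
        "n_pos": int(labels.sum()),
        "n_neg": int((~labels).sum()),
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))


def _stage_de(cfg: RunConfig, out: Path) -> None:
    matrix = genomic_io.read_expression(out / "expression.tsv")
    de = expression.select_de_genes(matrix, cfg.fold_cutoff)
    fdr = expression.permutation_fdr(matrix, cfg.fold_cutoff, n_perm=cfg.n_perm, seed=cfg.seed)
    clusters = expression.cluster_de_genes(matrix, de, k=cfg.k_clusters, seed=cfg.seed)
    de.table.reset_index(names="gene").to_csv(out / "de_table.tsv", sep="\t", index=False)
    clusters.assignments.rename_axis("gene").reset_index().to_csv(
        out / "de_clusters.tsv", sep="\t", index=False
    )
    (out / "fdr.json").write_text(
        json.dumps(
            {
                "observed": fdr.observed,
                "permuted_mean": fdr.permuted_mean,
                "fdr": fdr.fdr,
                "n_perm": fdr.n_perm,
                "cluster_coherence": clusters.coherence,
            },
            indent=2,
            sort_keys=True,
        )
    )


def _stage_tfscore(cfg: RunConfig, out: Path) -> None:
    posteriors = {
        t: genomic_io.read_predictions(out / f"posteriors_{label}.tsv")
        for t, label in ((0.0, "0h"), (6.0, "6h"), (24.0, "24h"))
    }
    accessible = tfscore.accessible_motifs(posteriors)
    rpm_tables = {
        label: pd.read_csv(out / f"features_{label}.tsv", sep="\t").set_index("motif_index")["rpm"]
        for label in ("0h", "6h", "24h")
    }
    rpm_by_pwm = {}
    for pwm_id, sub in accessible.groupby("pwm_id"):
        idx = sub["motif_index"]
        rpm_by_pwm[pwm_id] = pd.DataFrame(
            {
                "rpm_0h": rpm_tables["0h"].reindex(idx).to_numpy(),
                "rpm_6h": rpm_tables["6h"].reindex(idx).to_numpy(),
                "rpm_24h": rpm_tables["24h"].reindex(idx).to_numpy(),
            }
        )
    tss = genomic_io.read_tss(out / "tss.tsv")
    matrix = genomic_io.read_expression(out / "expression.tsv")
    de_table = pd.read_csv(out / "de_table.tsv", sep="\t").set_index("gene")
    cluster_table = pd.read_csv(out / "de_clusters.tsv", sep="\t")
    clusters = {
        int(cid): sub["gene"].tolist() for cid, sub in cluster_table.groupby("cluster")
    }
    background = de_table.index[
        ~de_table["selected"] & matrix.expressed.reindex(de_table.index).fillna(False)
    ].tolist()
    up = expression.call_upregulated_factors(matrix, cfg.fold_cutoff)
    # one member factor per PWM in the fixture world: the PWM's eponymous gene
    pwm_ids = sorted(accessible["pwm_id"].unique())
    genes = list(matrix.genes[: len(pwm_ids)])
    family_table = pd.DataFrame(
        {"pwm_id": pwm_ids, "gene": genes, "family": pwm_ids}
    )
    level = matrix.replicate_means().mean(axis=1)
    scores, audit = tfscore.score_factors(
        accessible,
        rpm_by_pwm,
        tss,
        clusters,
        background,
        up,
        family_table,
        level,
        rubric=cfg.rubric,
        max_distance=cfg.max_motif_gene_distance,
    )
    genomic_io.write_tfscores(out / "tfscores.tsv", scores)
    (out / "tfscore_audit.json").write_text(json.dumps(audit, indent=2, sort_keys=True))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "features": _stage_features,
    "fit": _stage_fit,
    "predict": _stage_predict,
    "evaluate": _stage_evaluate,
    "de": _stage_de,
    "tfscore": _stage_tfscore,
}

_ARTIFACTS = {
    "simulate": [
        "motifs.bed", "tags_0h.bed", "tags_6h.bed", "tags_24h.bed",
        "conservation.bedgraph", "tss.tsv", "peaks.bed", "truth.tsv",
        "expression.tsv", "expression_truth.tsv", "scenario.json",
    ],
    "features": ["features_0h.tsv", "features_6h.tsv", "features_24h.tsv"],
    "fit": ["params.json", "fit_report.json", "train.tsv", "test.tsv"],
    "predict": [
        "posteriors_0h.tsv", "posteriors_6h.tsv", "posteriors_24h.tsv",
        "posteriors_test.tsv",
    ],
    "evaluate": ["metrics.json"],
    "de": ["de_table.tsv", "de_clusters.tsv", "fdr.json"],
    "tfscore": ["tfscores.tsv", "tfscore_audit.json"],
}


def run_full(cfg: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in order and write a checksum manifest.

    Returns the manifest dict (stage -> artifact -> sha256).  A stage
    failure aborts with the stage name in the raised error's context.
    """
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigurationError(f"unknown stages: {unknown}")
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}}
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.monotonic()
        try:
            _STAGE_FUNCS[stage](cfg, out)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        checksums = {}
        for name in _ARTIFACTS[stage]:
            path = out / name
            if path.exists():
                checksums[name] = _sha256(path)
        manifest["stages"][stage] = checksums
        log.info("stage %s done in %.2fs", stage, time.monotonic() - t0)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
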