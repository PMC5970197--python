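"""Synthetic data: motif features, fixture genome files, expression matrices.

The generator inverts the binding model's own generative story so every
downstream module can be exercised without any external download: motif
features (f, d, c) are drawn from simple bounded distributions, the
hidden binding state from the logistic prior, and flanking tag counts
from the state's negative binomial.  A fixture "genome" lays the same
motifs out on one pseudo-chromosome with tags, conservation intervals,
TSSs and ChIP-like peaks over the truly bound motifs, so feature
extraction and evaluation labels can be validated against the simulated
truth exactly.  The default parameters separate bound and unbound mean
tag counts about 20-fold, the regime in which the model is intended to
operate on real accessibility data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .genomic_io import (
    ConservationTrack,
    GenomicInterval,
    TagTrack,
    TSSTable,
    write_bedgraph,
    write_motif_bed,
    write_peaks,
    write_tag_bed,
    write_tss,
)
from .features import MotifSite
from .model import ModelParams, e_step, logistic_prior

__all__ = [
    "SimulationScenario",
    "DEFAULT_TRUE_PARAMS",
    "simulate_motif_dataset",
    "simulate_genome_fixture",
    "simulate_expression_timecourse",
    "simulate_knockdown_lfc",
]

# bound mean 5*0.8/0.2 = 20 tags vs unbound 1*0.5/0.5 = 1 tag (~20x)
DEFAULT_TRUE_PARAMS = ModelParams(
    beta0=-2.0, beta1=2.0, beta2=1.5, beta3=1.0, K0=1.0, r0=0.5, K1=5.0, r1=0.8
)

TIMEPOINTS_H = (0, 1, 2, 4, 8, 12, 16, 24)


@dataclass
class SimulationScenario:
    """All knobs of the synthetic study, with field-realistic defaults."""

    n_motifs: int = 20000
    true_params: ModelParams = field(default_factory=lambda: DEFAULT_TRUE_PARAMS)
    # feature distributions: f, d uniform on (0,1); c Beta(2,2)
    c_beta: tuple[float, float] = (2.0, 2.0)
    seed: int = 0
    genome_length: int = 20_000_000
    n_pwms: int = 5
    motif_length: int = 10
    motif_spacing: int = 800
    n_genes: int = 2000
    de_fraction: float = 0.07
    fold_change_range: tuple[float, float] = (1.8, 4.0)
    replicate_noise_sd: float = 0.1
    accessibility_gain: tuple[float, float] = (2.0, 4.0)  # 6 h / 24 h fold for bound motifs

    def __post_init__(self) -> None:
        if self.n_motifs <= 0 or self.n_genes <= 0:
            raise ConfigurationError("n_motifs and n_genes must be positive")
        if not (0 <= self.de_fraction <= 1):
            raise ConfigurationError("de_fraction must lie in [0, 1]")
        if min(self.fold_change_range) <= 0:
            raise ConfigurationError("fold changes must be positive")
        if self.replicate_noise_sd < 0:
            raise ConfigurationError("replicate noise sd must be non-negative")
        if min(self.c_beta) <= 0:
            raise ConfigurationError("Beta parameters must be positive")
        self.true_params.__post_init__()  # re-validate NB/logistic ranges

    def to_json(self, path) -> None:
        d = asdict(self)
        d["true_params"] = self.true_params.to_dict()
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SimulationScenario":
        d = json.loads(Path(path).read_text())
        d["true_params"] = ModelParams.from_dict(d["true_params"])
        for key in ("c_beta", "fold_change_range", "accessibility_gain"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _draw_counts(rng, params: ModelParams, b: np.ndarray) -> np.ndarray:
    """Tag counts from the state-conditional negative binomials."""
    n = np.empty(b.size, dtype=np.int64)
    unbound = ~b.astype(bool)
    # numpy's negative_binomial(n, p) counts failures with success prob p
    n[unbound] = rng.negative_binomial(params.K0, 1 - params.r0, size=int(unbound.sum()))
    n[~unbound] = rng.negative_binomial(params.K1, 1 - params.r1, size=int(b.sum()))
    return n


def simulate_motif_dataset(scenario: SimulationScenario) -> pd.DataFrame:
    """Draw a motif feature table with true states and true posteriors.

    Returns one row per motif with f, d, c, n, the latent state ``b``,
    the prior ``y_true`` and the posterior ``gamma_true`` implied by the
    true parameters (the quantity a perfect fit would recover).
    """
    rng = np.random.default_rng(scenario.seed)
    p = scenario.true_params
    f = rng.uniform(0, 1, scenario.n_motifs)
    d = rng.uniform(0, 1, scenario.n_motifs)
    c = rng.beta(*scenario.c_beta, scenario.n_motifs)
    y = logistic_prior(p, f, d, c)
    b = rng.random(scenario.n_motifs) < y
    n = _draw_counts(rng, p, b)
    table = pd.DataFrame(
        {
            "motif_index": np.arange(scenario.n_motifs),
            "pwm_id": [f"PWM{i % scenario.n_pwms + 1}" for i in range(scenario.n_motifs)],
            "f": f,
            "d": d,
            "c": c,
            "n": n,
            "b": b.astype(int),
            "y_true": np.asarray(y),
        }
    )
    table["gamma_true"] = e_step(p, table)
    return table


def simulate_genome_fixture(scenario: SimulationScenario, outdir) -> dict:
    """Lay out a pseudo-chromosome and write every fixture file.

    Motifs sit at fixed spacing on one chromosome ("chrS"); gene TSSs are
    placed uniformly, so TSS distances (hence d) come from the actual
    layout rather than being drawn.  Exactly n_i tags are placed in each
    flanking window of motif i (so the windowed minimum recovers n_i),
    scaled-up tag tracks are written for the 6 h and 24 h time points
    (bound motifs gain accessibility), and ChIP-like peaks cover exactly
    the bound motifs.  Returns the truth table and file paths.
    """
    if scenario.genome_length < 10_000:
        raise ConfigurationError("genome_length must be >= 10 kb")
    spacing = scenario.motif_spacing
    need = (scenario.n_motifs + 1) * spacing + 1000
    if scenario.genome_length < need:
        raise ConfigurationError(
            f"genome_length {scenario.genome_length} too small for "
            f"{scenario.n_motifs} motifs at spacing {spacing} (need >= {need})"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(scenario.seed)
    p = scenario.true_params
    chrom = "chrS"
    L = scenario.motif_length
    window = 200

    starts = spacing * (1 + np.arange(scenario.n_motifs))
    ends = starts + L
    mids = (starts + ends) // 2

    # genes: uniform TSS positions over the used span
    span = int(starts[-1] + spacing)
    tss_pos = np.sort(rng.integers(0, span, scenario.n_genes))
    genes = [f"G{i+1:05d}" for i in range(scenario.n_genes)]
    tss_table = TSSTable(
        pd.DataFrame(
            {
                "gene": genes,
                "chrom": chrom,
                "tss": tss_pos,
                "strand": np.where(rng.random(scenario.n_genes) < 0.5, "+", "-"),
                "expressed": True,
            }
        )
    )

    # features from the layout + draws
    f = rng.uniform(0, 1, scenario.n_motifs)
    c = np.round(rng.beta(*scenario.c_beta, scenario.n_motifs), 4)
    tss_dist = np.array([tss_table.nearest(chrom, int(m))[0] for m in mids])
    d = 1.0 / (1.0 + tss_dist / 1000.0)
    y = logistic_prior(p, f, d, c)
    b = rng.random(scenario.n_motifs) < y
    n = _draw_counts(rng, p, b)

    pwm_ids = np.array([f"PWM{i % scenario.n_pwms + 1}" for i in range(scenario.n_motifs)])
    truth = pd.DataFrame(
        {
            "motif_index": np.arange(scenario.n_motifs),
            "pwm_id": pwm_ids,
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "fimo_score": 10.0 + 10.0 * f,
            "tss_distance": tss_dist,
            "f": f,
            "d": d,
            "c": c,
            "n": n,
            "b": b.astype(int),
            "y_true": np.asarray(y),
        }
    )
    truth["gamma_true"] = e_step(p, truth)

    # tag tracks: n_i tags in each flanking window at 0 h; bound motifs
    # gain accessibility at 6 h and 24 h
    def tag_positions(counts: np.ndarray) -> np.ndarray:
        pos = []
        for s, e, k in zip(starts, ends, counts):
            if k <= 0:
                continue
            left = rng.integers(s - window, s, k)
            right = rng.integers(e, e + window, k)
            pos.append(left)
            pos.append(right)
        return np.concatenate(pos) if pos else np.array([], dtype=np.int64)

    gain6, gain24 = scenario.accessibility_gain
    counts_by_time = {
        "0h": n,
        "6h": np.where(b, rng.poisson(n * gain6), n),
        "24h": np.where(b, rng.poisson(n * gain24), n),
    }
    paths = {}
    for label, counts in counts_by_time.items():
        track = TagTrack({chrom: tag_positions(counts)})
        paths[f"tags_{label}"] = outdir / f"tags_{label}.bed"
        write_tag_bed(paths[f"tags_{label}"], track)

    # conservation over each motif interval
    cons = ConservationTrack({chrom: [(int(s), int(e), float(v)) for s, e, v in zip(starts, ends, c)]})
    paths["conservation"] = outdir / "conservation.bedgraph"
    write_bedgraph(paths["conservation"], cons)

    # motif BED and TSS table
    sites = [
        MotifSite(GenomicInterval(chrom, int(s), int(e), "+"), pid, float(fs))
        for s, e, pid, fs in zip(starts, ends, pwm_ids, truth["fimo_score"])
    ]
    paths["motifs"] = outdir / "motifs.bed"
    write_motif_bed(paths["motifs"], sites)
    paths["tss"] = outdir / "tss.tsv"
    write_tss(paths["tss"], tss_table)

    # one ChIP-like peak per bound motif (margin < inter-motif gap)
    margin = 50
    peaks = [
        GenomicInterval(chrom, int(s) - margin, int(e) + margin)
        for s, e, bound in zip(starts, ends, b)
        if bound
    ]
    paths["peaks"] = outdir / "peaks.bed"
    write_peaks(paths["peaks"], peaks)

    paths["truth"] = outdir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    return {"truth": truth, "paths": {k: str(v) for k, v in paths.items()}}


_ARCHETYPES = ("continuous_up", "early_up", "intermediate_up", "continuous_down")


def _archetype_profile(name: str, times: np.ndarray, log2_fold: float) -> np.ndarray:
    """Log2 trajectory of one DE archetype over the time course."""
    t = times / times.max()
    if name == "continuous_up":
        shape = t
    elif name == "early_up":
        shape = np.minimum(times / 2.0, 1.0)  # saturates by 2 h
    elif name == "intermediate_up":
        shape = np.clip((times - 4.0) / 8.0, 0.0, 1.0)  # rises 4-12 h
    elif name == "continuous_down":
        shape = -t
    else:
        raise ValueError(name)
    return log2_fold * shape


def simulate_expression_timecourse(scenario: SimulationScenario):
    """Two-replicate expression time course with four DE archetypes.

    A ``de_fraction`` of genes follow one of four trajectory archetypes
    (continuously up, early up, intermediate up, continuously down) with
    a max |log2 fold| drawn from ``fold_change_range``; the rest are flat.
    Replicate noise is i.i.d. Gaussian on the log2 scale.  Returns the
    matrix plus the true DE labels and archetypes.
    """
    from .expression import ExpressionMatrix

    rng = np.random.default_rng(scenario.seed + 1)
    times = np.array(TIMEPOINTS_H, dtype=float)
    genes = [f"G{i+1:05d}" for i in range(scenario.n_genes)]
    n_de = int(round(scenario.de_fraction * scenario.n_genes))
    de_idx = rng.choice(scenario.n_genes, size=n_de, replace=False)
    archetypes = np.array([""] * scenario.n_genes, dtype=object)
    archetypes[de_idx] = rng.choice(_ARCHETYPES, size=n_de)

    base = rng.lognormal(mean=5.0, sigma=1.0, size=scenario.n_genes)
    lo, hi = scenario.fold_change_range
    log2_profiles = np.zeros((scenario.n_genes, times.size))
    for i in de_idx:
        fold = rng.uniform(lo, hi)
        log2_profiles[i] = _archetype_profile(archetypes[i], times, np.log2(fold))

    data = {}
    for j, t in enumerate(times):
        for rep in (1, 2):
            noise = rng.normal(0, scenario.replicate_noise_sd, scenario.n_genes)
            data[(t, rep)] = base * 2.0 ** (log2_profiles[:, j] + noise)
    values = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    values.columns = pd.MultiIndex.from_tuples(values.columns, names=["time", "rep"])
    matrix = ExpressionMatrix(values, pd.Series(True, index=values.index))
    labels = pd.DataFrame(
        {"de": archetypes != "", "archetype": archetypes}, index=values.index
    )
    return matrix, labels


def simulate_knockdown_lfc(
    n_genes: int = 2000,
    n_conditions: int = 6,
    common_fraction: float = 0.1,
    effect_log2: float = 2.0,
    noise_sd: float = 0.5,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Knockdown log2 fold-change matrix with a shared-response gene set.

    A ``common_fraction`` of genes respond in the same direction in every
    condition (half up, half down at ``effect_log2``); the rest are noise.
    """
    rng = np.random.default_rng(seed)
    lfc = rng.normal(0, noise_sd, (n_genes, n_conditions))
    n_common = int(round(common_fraction * n_genes))
    idx = rng.choice(n_genes, size=n_common, replace=False)
    sign = np.where(np.arange(n_common) % 2 == 0, 1.0, -1.0)
    lfc[idx] += (sign * effect_log2)[:, None]
    truth = pd.Series("none", index=[f"G{i+1:05d}" for i in range(n_genes)])
    truth.iloc[idx[sign > 0]] = "up"
    truth.iloc[idx[sign < 0]] = "down"
    frame = pd.DataFrame(
        lfc,
        index=truth.index,
        columns=[f"KD{j+1}" for j in range(n_conditions)],
    )
    return frame, truth
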