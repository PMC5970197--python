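"""Extract model features from fixture genome files.

Writes a small simulated pseudo-genome (motif BED, DNase tag BED,
conservation bedGraph, TSS table), then recomputes the per-motif
features f, d, c, n from the files and checks them against the
simulation's own record.
"""

import numpy as np

import accesstf as a
from accesstf import features as ft, genomic_io as gio

scenario = a.SimulationScenario(
    n_motifs=2000, n_genes=300, genome_length=3_000_000, seed=7
)
result = a.simulate_genome_fixture(scenario, "example_fixture")
truth = result["truth"]

motifs = gio.read_motif_table("example_fixture/motifs.bed", dialect="bed")
tags = gio.read_tag_bed("example_fixture/tags_0h.bed")
cons = gio.read_bedgraph("example_fixture/conservation.bedgraph")
tss = gio.read_tss("example_fixture/tss.tsv")

feats = ft.extract_features(motifs, tags, cons, tss)
print(feats[["pwm_id", "f", "d", "c", "n"]].head())
exact_n = (feats["n"].to_numpy() == truth["n"].to_numpy()).mean()
print(f"fraction of motifs with exactly recovered tag count: {exact_n:.3f}")
print(f"max |d - d_true| = {np.abs(feats['d'] - truth['d']).max():.2e}")
# f is the rescaled motif match score, d the TSS-proximity squash, c the
# mean conservation over the motif, n the min flanking DNase tag count.
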