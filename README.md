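# accesstf

Predict which DNA sequence motifs are actually bound by transcription
factors in vivo, using chromatin accessibility — and rank transcription
factors by their predicted importance for a biological transition.

Genome-wide motif scans report millions of candidate binding sites, of
which only a small fraction are occupied in any given cell state. This
package infers per-motif binding probabilities by combining DNase-seq
accessibility with motif quality, TSS proximity and evolutionary
conservation, and then integrates the predicted bound motifs with
differential accessibility and expression data into a score that
rank-orders transcription factors as candidate drivers of a transition
(the motivating system is tamoxifen-induced oncogenic transformation of
ER-Src breast epithelial cells). It is a library first, with a thin
`accesstf` command-line wrapper and narrative scripts under `examples/`.

## The model

Each candidate motif *i* carries four observables:

- *f<sub>i</sub>* = (FIMO score − 10)/10, clamped to [0, 1] — motif match quality;
- *d<sub>i</sub>* = 1/(1 + TSS_dist<sub>i</sub>/1000) — proximity to the nearest transcription start site;
- *c<sub>i</sub>* — mean per-base conservation (PhastCons-style) over the motif;
- *n<sub>i</sub>* — the *smaller* of the DNase tag counts in the 200 bp windows
  flanking the motif (the minimum penalises motifs at the edge of an
  accessible region).

The binding state *b<sub>i</sub>* ∈ {0, 1} is hidden. Its prior is logistic in the
sequence-level features,

&nbsp;&nbsp;&nbsp;&nbsp;logit *y<sub>i</sub>* = β₀ + β₁ *f<sub>i</sub>* + β₂ *d<sub>i</sub>* + β₃ *c<sub>i</sub>*,&nbsp;&nbsp;&nbsp;&nbsp;*y<sub>i</sub>* = P(*b<sub>i</sub>* = 1),

and the tag count is negative-binomial conditional on the state,

&nbsp;&nbsp;&nbsp;&nbsp;P(*n* | *b* = s) = C(*n* + *K<sub>s</sub>* − 1, *n*) (1 − *r<sub>s</sub>*)<sup>*K<sub>s</sub>*</sup> *r<sub>s</sub>*<sup>*n*</sup>,&nbsp;&nbsp;&nbsp;&nbsp;mean *K<sub>s</sub>r<sub>s</sub>*/(1 − *r<sub>s</sub>*).

All eight parameters (β₀–β₃, K₀, r₀, K₁, r₁) are estimated by EM,
initialized by calling the top 5% of motifs by tag count bound. The
output per motif is the posterior γ<sub>i</sub> = P(*b<sub>i</sub>* = 1 | *f, d, c, n*).

The TF ranking (`accesstf.tfscore`) then sums four criteria per PWM and
member factor: accessibility gain around bound motifs at 6 h and 24 h
(0–5 points each), enrichment of bound motifs near differentially
expressed gene clusters by one-sided Fisher exact test (0–5), +15 if the
factor itself is consistently up-regulated ≥ 1.5-fold, and a within-family
relative-expression band score (−10 to +5).

## Worked example

```python
import accesstf as a
from accesstf import evaluation as ev, model as md

scenario = a.SimulationScenario(seed=1)          # 20,000 motifs, ~20x separation
table = a.simulate_motif_dataset(scenario)
train, test = md.split_train_test(table, 10000, 10000, seed=1)
params, report = md.fit_em(train, seed=1)
pred = md.predict(params, test)
print(ev.roc_auc(pred["gamma"], test["b"]), ev.pr_auc(pred["gamma"], test["b"]))
```

Running `python examples/01_fit_binding_model.py` prints:

```
EM converged in 63 iterations
unbound NB mean 1.03 (true 1.00)
bound   NB mean 20.09 (true 20.00)
held-out ROC AUC 0.997
held-out PR  AUC 0.998
posterior correlation with truth 1.000
```

i.e. on held-out motifs the fitted posterior ranks truly bound motifs
almost perfectly, and the recovered negative-binomial component means
match the generating values within a few percent. The other examples
cover feature extraction from genome files (`02`), DE calling,
permutation FDR and trajectory clustering (`03`), and the end-to-end
factor ranking (`04`).

The same flow is available from the shell:

```bash
accesstf simulate --outdir sim --seed 1
accesstf extract-features --motifs sim/motifs.bed --dialect bed \
    --tags sim/tags_0h.bed --conservation sim/conservation.bedgraph \
    --tss sim/tss.tsv --out sim/features.tsv
accesstf fit --features sim/features.tsv --params-out sim/params.json
accesstf predict --params sim/params.json --features sim/features.tsv --out sim/post.tsv
accesstf evaluate --posteriors sim/post.tsv --peaks sim/peaks.bed --out sim/metrics.json
```

or in one shot via `accesstf run --config run.yaml` (see
`accesstf.pipeline.RunConfig`).

## Layout

- `src/accesstf/genomic_io.py` — BED / bedGraph / FIMO / TSV readers and writers (0-based half-open everywhere)
- `src/accesstf/features.py` — per-motif features and open-region chromatin-state classification
- `src/accesstf/model.py` — the latent-state binding model and EM
- `src/accesstf/evaluation.py` — peak-overlap labels, ROC/PR AUC, posterior calibration bins
- `src/accesstf/expression.py` — DE selection, permutation FDR, K-means trajectory clusters, knockdown consistency
- `src/accesstf/tfscore.py` — the four-criterion factor ranking
- `src/accesstf/synthetic_data.py` — the simulation scenarios behind all tests
- `src/accesstf/pipeline.py`, `src/accesstf/cli.py` — orchestration and the `accesstf` command
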