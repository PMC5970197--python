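# Methods

## The binding model

Every candidate motif carries a hidden binding state `b ∈ {0, 1}`. The
model is a two-node Bayesian network: the sequence-level features
(match quality `f`, TSS proximity `d`, conservation `c`) determine the
prior on `b` through a logistic link, and `b` determines the
distribution of the flanking DNase tag count `n` through one of two
negative-binomial emissions:

    logit P(b=1) = β0 + β1 f + β2 d + β3 c
    n | b=s ~ NB(K_s, r_s),  pmf C(n+K−1, n) (1−r)^K r^n,  mean K r/(1−r)

Assumptions worth stating explicitly:

- Motifs are treated as independent: no joint occupancy, no footprint
  shape, no competition between overlapping motifs. Duplicated or
  overlapping matches of one PWM are kept as separate observations.
- The NB is used with a gamma-function pmf, so non-integer `K` is
  allowed; `n` is an integer count (the minimum of the two one-sided
  window counts, which penalises motifs at accessible-region edges).
- β3 (conservation) is estimated jointly with the other coefficients:
  the logistic link includes all three features.

### Fitting

Parameters are estimated by EM. The E-step computes responsibilities

    γ_i = y_i NB(n_i|K1,r1) / [ y_i NB(n_i|K1,r1) + (1−y_i) NB(n_i|K0,r0) ]

in log space (component log-likelihoods floored at log 1e−300; if the
emissions are identical the responsibility reduces to the prior
exactly). The M-step refits:

- the β's by maximising the γ-weighted Bernoulli log-likelihood
  (fractional responses) with BFGS, warm-started from the previous
  iterate so the expected complete-data objective cannot decrease;
- each NB component by weighted maximum likelihood with `r` profiled
  out at its closed-form optimum `r = m/(m+K)` (weighted mean `m`),
  leaving a bounded 1-D search over `log K` in [−12, 12].

Initialization sets γ = 1 for the motifs in the top 5% by tag count
(ties at the cutoff included) and 0 elsewhere; degenerate count vectors
(all equal) are rejected. Convergence is declared at relative
log-likelihood change ≤ 1e−6 (default), capped at 500 iterations. The
observed-data log-likelihood is checked to be non-decreasing at every
step and a decrease is a hard error, since EM guarantees monotonicity —
this is asserted inside `fit_em`, not just in tests. Hard "bound" calls
default to γ ≥ 0.99 and the threshold is configurable; it is a
reporting convenience, not part of the model.

Train/test splitting defaults to 10,000/10,000 motifs sampled uniformly
without replacement, scaled down proportionally (with a warning) on
smaller inputs.

## Feature conventions

- Coordinates are 0-based half-open everywhere internally; FIMO tables
  (1-based inclusive) are converted on read.
- A tag is counted at the position in its BED start field; tag strand
  is ignored. Flanking windows are `[start−200, start)` and
  `[end, end+200)` on the reference strand (motif strand ignored),
  truncated at the chromosome start.
- `f = (FIMO score − 10)/10` clamped into [0, 1]: real score
  distributions extend below 10 and above 20, and clamping keeps the
  feature in its declared range.
- TSS distance is measured from the motif midpoint to the nearest
  annotated TSS over **all** genes; the expressed-gene filter applies
  only in the ranking stage's motif→gene assignment.
- Conservation over uncovered bases defaults to 0 (conservative).
- Open regions are classified by histone-mark overlap with the
  precedence K27ac∧K4me3 → active promoter; K27ac → active enhancer;
  K4me1 → primed enhancer; K9me3∨K27me3 → heterochromatin/polycomb;
  otherwise "other" — mutually exclusive and exhaustive by construction.

## Evaluation

Motifs overlapping a peak by ≥ 1 bp (configurable) are positives. ROC
AUC is the rank statistic (ties count one half); PR AUC is the area
under the step precision–recall curve with no interpolation between
operating points — both are stated so numbers are comparable across
implementations, and both are cross-checked in the test suite against
brute-force pair enumeration and a manual threshold sweep.

## Expression analysis

A gene is differentially expressed when, at ≥ 1 non-baseline time
point, *both* replicate fold changes against the baseline replicate
mean exceed the cutoff (default 1.5) in the same direction. Each
replicate is compared to the baseline mean (the pairing of replicates
across time points is arbitrary on arrays). Genes with zero baseline
are excluded with a warning; unexpressed genes are never selected.

The selection rule's FDR is estimated by independently permuting every
fold-change column (time × replicate) across genes and re-applying the
rule; the estimate is mean permuted count / observed count. The default
is 100,000 permutations; the pipeline default and the tests use
500–2,000, which reproduce the estimate within Monte-Carlo error.

Two properties of this randomization scheme are worth knowing:

- it assumes fold-change values are exchangeable across genes *within a
  column*; shared baseline noise (one noisy baseline dividing all of a
  gene's fold changes) correlates the two replicate fold changes of a
  gene and makes the observed count exceed the permuted mean even with
  no signal. The null-calibration tests therefore use a null matrix
  whose fold changes are i.i.d. across genes;
- with dense, strong signal the permuted null inherits the many large
  fold-change values, so the FDR estimate is conservative rather
  than ≪ 1; it approaches 0 when true DE genes are sparse.

Selected genes are standardized per gene (mean 0, unit variance over
the per-time replicate means) and clustered by K-means with k = 4 and
50 restarts (best inertia, seeded). Cluster coherence is summarized as
the median within-cluster pairwise Pearson correlation; values above
0.7 indicate a coherent trajectory shape.

The knockdown consistency statistic is the fraction of genes whose
log2 fold change exceeds a threshold (default 1, i.e. 2-fold) in the
same direction in *all* conditions, compared against a background from
independently permuting each condition's column.

## Factor ranking

Per PWM, the four criteria and their defaults:

1. **Accessibility gain.** For each bound ("accessible") motif, RPM =
   (upstream + downstream window tag counts)/library × 10⁶. The per-PWM
   statistic at time t is Σ over motifs of RPM_t/RPM_0; a zero baseline
   contributes RPM_t over a one-read-scale pseudocount so newly opened
   sites still count. 6 h bin edges: 600/1000/1500/3000/5000 → 0–5
   points. The printed 24 h bins in the original description are
   internally non-monotone (an apparent typo); the default here keeps
   the first two printed 24 h bins (≤2000 → 0, 2001–4000 → 1) and
   extends the 6 h structure: 2000/4000/6000/9000/15000. **This is a
   correction choice** and the edges are fully configurable via
   `ScoreRubric`.
2. **Cluster enrichment.** Accessible motifs are assigned to the
   nearest *expressed* gene's TSS within 100 kb (20 kb available by
   flag). One one-sided Fisher exact test per DE cluster against the
   non-DE expressed background; the criterion uses the best cluster's
   −log10 P, binned at 8/11/14/17/20 → 0–5 points. Using the best
   cluster (rather than a combined statistic) is a design choice.
3. **Up-regulation.** +15 if the factor itself passes the
   replicate-consistent 1.5-fold up rule at any time point.
4. **Family expression.** With family maximum E: +5 at E, +3 in
   (E/2, E), 0 in (E/4, E/2], −5 in (E/6, E/4], −10 at or below E/6.
   Boundary closure (upper bounds inclusive in the lower band) is a
   documented choice; an all-zero family scores −10 throughout with a
   warning.

The total is the plain sum; ties are broken by factor name so the
ranked table is deterministic.

## Synthetic data

The generator inverts the model's own generative story. Defaults:
f, d ~ Uniform(0,1); c ~ Beta(2,2) (the real-data feature distributions
are not published, so these are coverage-oriented stand-ins, exposed in
the scenario config); β = (−2, 2, 1.5, 1); unbound NB (K=1, r=0.5),
mean 1 tag; bound NB (K=5, r=0.8), mean 20 tags. The ~20× separation of
component means is the regime the method is designed for on real
accessibility data; 20,000 motifs support the default 10,000/10,000
train/test split.

The fixture genome lays motifs at 800 bp spacing on one
pseudo-chromosome ("chrS"), places gene TSSs uniformly and derives `d`
from the actual layout, writes exactly `n_i` tags into each flanking
window (so windowed counting recovers `n_i` exactly), scales bound-motif
tag counts by Poisson-sampled gains at 6 h and 24 h, and puts one
ChIP-like peak (±50 bp) over each truly bound motif so peak-overlap
labels equal the true states. The expression simulator injects four
trajectory archetypes (continuous up, early up at 2 h, intermediate up
rising 4–12 h, continuous down) into a `de_fraction` (default 0.07) of
genes with multiplicative log-normal replicate noise (default sd 0.1 on
the log2 scale), over the 0–24 h 8-point design with two replicates.

What passing tests on this synthetic world do **not** show: real DNase
data have fragment-level artefacts, copy-number and mappability biases,
and motif features that are correlated with each other and with
accessibility in ways the independent draws here do not emulate; real
expression arrays have intensity-dependent variance. Synthetic AUCs
near 1 therefore demonstrate correctness of the estimation machinery,
not expected real-data performance.

## Problem sizes and numerics

Default test and acceptance runs use 10,000–20,000 motifs, 10 recovery
seeds, and a few hundred FDR permutations — sizes chosen so a full
desk-scale study (simulate → fit → evaluate → rank) completes in well
under a minute per fit on a single core. Component likelihood floors
(1e−300), the bounded `log K` search, tie handling at the
initialization cutoff, and the γ-saturation of posteriors at exactly
1.0 in floating point are the notable numerical details; degenerate
inputs (all-equal counts, empty families, single-class labels) raise
typed errors rather than returning silent defaults.

## Known limitations

- Binding probabilities are per-motif and marginal; no multi-factor or
  cooperative occupancy.
- The model cannot identify factors recruited indirectly (tethered to
  sites without their own motif).
- The rubric's 24 h accessibility bins are a corrected reconstruction
  (see above), and the mapping from posterior to a stringent "bound"
  call is a configurable threshold rather than a calibrated p-value.
- The permutation FDR is exact only under across-gene exchangeability
  of fold-change columns (see the expression section).
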