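# Methods

## Model and assumptions

`crosspath` analyses a genes × samples matrix of log2-scale expression
values with exactly two sample groups (a reference/normal group and a
test/disease group; the reference is the first group listed in the
labels file). All statistics assume approximately Gaussian
log-expression within groups; identifiers are opaque case-sensitive
strings and no probe/gene mapping is performed. Genes that appear in
gene sets or PPI edges but not in the matrix are retained in their
containers and ignored by the statistics, with logged counts — this
mirrors the coverage gap between pathway/interaction databases and any
one platform rather than treating it as an error.

## DEG screen

The fold change is mean(test) − mean(reference) in log2 units. The
default test is a moderated two-group t: gene-wise pooled variances
s²_g (df = n₁+n₂−2) are shrunk toward the mean variance of all genes,
s̃²_g = (d₀·s̄² + df·s²_g)/(d₀+df), with a fixed prior weight d₀ = 4
pseudo-degrees of freedom, and t is referred to a t distribution with
df + d₀ degrees of freedom. This reproduces the variance-moderation
behaviour of empirical-Bayes microarray tests with one transparent
constant instead of a fitted hyperprior; d₀ is configurable and a
plain Welch t is available (`method="welch"`). Both thresholds are
applied inclusively (|log₂FC| ≥ 1.5, P ≤ 0.01) and the P value is
unadjusted — the screen's cut-off is defined on raw P, and its output
feeds the network filter rather than a formal inference.

## Attractor pathway statistics

Gene-level F is the standard one-way ANOVA ratio of the between-group
mean square to the residual (within-group) mean square. Genes with
zero residual variance get F = +∞ when group means differ (F = 0
otherwise) and are excluded from pathway means with a warning, so
degenerate inputs cannot propagate NaNs.

The pathway statistic treats the "sample aberrances" S_p², S_G² as
unbiased sample variances of the F values inside the pathway and over
the whole gene universe; T_p is then exactly a Welch two-sample t
between the pathway's F values and all genes' F values. The default
reference distribution is a t with Welch–Satterthwaite degrees of
freedom, two-sided. The gene universe G defaults to every gene in the
expression matrix (`universe="sets"` restricts it to pathway members).

Two caveats are deliberate and documented rather than hidden:

* the pathway is a subset of the universe it is compared against, and
  gene F values are strongly right-skewed (for two groups F has one
  numerator df), so the t reference is only approximate for small
  pathways — in null simulations its left tail is inflated roughly
  twofold at P < 0.05. A permutation reference
  (`method="permutation"`, random same-size gene sets, seeded) is
  exact by construction and is what the calibration test uses; the t
  reference remains the fast default for ranking, where the
  monotone T → P mapping is what matters.
* the statistic is competitive: with very strong planted signal the
  genome-wide mean F rises, and pathways containing *no* perturbed
  gene can appear significantly depleted (large negative T) under the
  two-sided P. This is a genuine property of competitive gene-set
  tests, visible in synthetic studies with zero overlap between
  planted and null pathways.

BH adjustment is the standard step-up: q₍ᵢ₎ = min_{j≥i} p₍ⱼ₎·m/j,
capped at 1. Selection downstream uses the raw P by default (the
printed selection rule is stated on P values; `--use-fdr` switches to
the adjusted column, which is always emitted).

## Cross-talk networks

Per-group Spearman coefficients are rank-Pearson correlations with
average ranks on ties, computed from that group's samples only; each
group needs ≥ 3 samples. Edges with a gene constant within a group
(undefined coefficient) are excluded with a logged count. mean_r is
computed and reported but drives no filter. An edge is retained for
the disease network iff |Δr| ≥ 0.5 (inclusive) or both endpoints are
DEGs.

The pathway-pair weight is the number of *distinct* input gene pairs
with one endpoint in each pathway; a gene pair spanning overlapping
pathways counts once for every such unordered pathway pair, and a
pair internal to one pathway contributes nothing (no self-loops). The
threshold is strict (weight > 5 ⇒ keep at ≥ 6). The background
network uses all PPI edges under the same rule — consistent with the
near-complete background degrees in the published top-ten table —
while the disease network uses only retained edges. `count="multiset"`
offers the alternative reading in which repeated input records count
with multiplicity. The pathway score is degree_disease /
degree_background, defined as 0 (flagged) when the background degree
is 0.

## Integration

Rank products use average ranks on ties (min-rank by option), with
rank 1 for the smallest P and the largest degree — the high-degree
direction follows from degree being the measure of a pathway's
importance in the network. "Total" is the number of pathways actually
scored in the run. "outer" in IF = outer × (1 − inter) is the
disease-network degree. Core selection is strict: P < 0.05,
RP < 0.05, IF > 100; note RP ≥ 1/Total², so very small collections
cannot pass the RP cut by construction.

## Synthetic studies

The generator emulates a two-group tumour/normal cohort: gene-wise
baselines ~ N(8, 1.5²) log2 units, i.i.d. Gaussian noise (σ = 0.5 by
default), an additive group shift of ±3 log2 units on planted DEGs —
effect sizes typical of the strongly differential genes a microarray
screen retains. Planted DEGs are drawn from the member genes of the
planted differential pathways (80% of them by default), so those
pathways are enriched for signal without being pure.

Correlation structure is created by per-edge latent factors (unit
variance, loading 2σ, giving within-group Spearman ≈ 0.8 for an edge
that owns its factor). Rewired edges flip the loading sign of one
endpoint in the test group, so r₁ ≈ +0.8, r₂ ≈ −0.8 and |Δr| ≈ 1.6;
their endpoints are sampled without replacement so each rewired pair
owns its factor outright — a gene carrying many factors would dilute
every per-edge correlation below the 0.5 threshold. Remaining edges
receive shared same-sign factors greedily while both endpoints are
factor-free.

The disease module is hub-centred, as in scale-free interactomes: a
fraction (20%) of planted DEGs act as hubs, disease-module PPIs (40%
of the edge list by default) join a hub to another planted DEG, and
hubs are exclusive members of the planted pathways (a hub sampled
into a null pathway is swapped for a fresh gene). Exclusivity is what
bounds null-pathway disease degrees structurally: without it, hubs
leaking into null pathways let every null pathway inherit the
module's connectivity, and disease degrees no longer separate planted
from unplanted pathways. Remaining edges are uniform random pairs.

What the generator does **not** emulate: probe-level intensities and
normalisation artefacts, correlated noise/batch structure, realistic
library-size or intensity-dependent variance, scale-free global PPI
topology, or curated-pathway size distributions. Passing tests
therefore demonstrate the pipeline's internal correctness and its
ability to recover planted structure under the stated generative
model — not performance on real cohorts.

## Problem sizes and defaults

The shipped demo (also the generator's defaults) uses 2000 genes,
40 + 40 samples, 150 pathways of 40–70 genes with 6 planted, 12000
PPI edges, seed 7; it runs in about a second and its core set equals
the planted set with wide margins (planted IF ≈ 120–150 against null
IF < 10 across seeds). Calibration checks use 50 small null studies
(500 genes, 30 pathways, 20 + 20 samples) with the permutation
reference at 2000 permutations; recovery checks use 20 seeds of a
30-pathway configuration with overlapping sets (sizes 30–50 of 500
genes), where membership overlap keeps unaffected pathways' means
near the genome-wide mean (see the competitive-test caveat above).

## Known limitations

* The t reference for pathway T is anti-conservative for small gene
  sets; use the permutation reference when calibrated P values
  matter.
* The DEG-pair retention clause uses no correlation evidence; in a
  study with many DEGs it dominates the disease network.
* Weights count distinct gene pairs; interaction confidence scores
  (e.g. database edge weights) are not used.
* With heavily overlapping gene sets, a single gene pair legitimately
  supports many pathway pairs; pathway-pair weights are therefore not
  independent across pairs, and degrees should be read descriptively,
  not inferentially.
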