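# Methods

`fermnet` integrates independent fermented-vegetable 16S time-series
studies into a comparable set of ASV association networks, a core network
of associations shared across studies, and a cross-study clustering of
ASVs by a Poisson multiplex stochastic block model (SBM).  This note
records the model and procedure, the defaults and why they are what they
are, the numerical choices, and what the synthetic-data tests do and do
not establish.

## Per-study association networks

A study arrives as a count table (samples x ASVs), a six-rank taxonomy
and per-sample metadata (study id, sampling time in days, control flags).
ASV identity across studies is exact sequence equality, so "the same ASV"
always means the same amplicon sequence.

**Filters.** ASVs assigned to organelles (family Mitochondria, or
order/class Chloroplast) and negative-control samples are removed first.
Then, in order: samples with strictly more than `min_depth` = 15,000
reads are kept; among those, ASVs present (count > 0) in at least
`min_samples` = 3 samples *and* with mean relative abundance (zeros
included, over the kept samples) strictly greater than
`min_mean_relabund` = 1e-5 are kept.  Both thresholds are read strictly
("more than"); flags allow switching.  Fewer than two surviving samples
is a hard error, since no pairwise statistic is estimable.

**The four association measures.** For every ASV pair the package
computes

* Jaccard distance on presence/absence, `1 - |x AND y| / |x OR y|`
  (two never-present ASVs are assigned distance 1: no co-presence
  evidence);
* Pearson and Spearman correlation of relative abundances;
* the proportionality statistic `phi(a, b) = var(clr a - clr b) /
  var(clr a + clr b)` on centered log-ratio (clr) transformed counts,
  sample variances with n-1.

An edge is drawn when at least one measure reaches its deliberately
non-stringent threshold — Jaccard distance <= 0.4, r >= 0.5 for either
correlation, phi <= 0.5 — and `support` (1-4) counts how many agreed.
Direction conventions: "reaching" the Jaccard threshold is read as the
distance falling *below* 0.4 (a similarity >= 0.4 option is provided,
since a distance "reaching a threshold" is ambiguous); small phi means
proportional, so phi passes *below* 0.5; correlations are signed by
default (positive co-abundance is the interpretive frame; an
absolute-value option exists).  Metrics undefined on a pair
(zero-variance profiles, anti-proportional clr vectors) count as failing,
never as passing.  Metrics are computed over all kept samples of a study,
not per time point.

**clr transform.** Default is the deterministic pseudocount mode,
clr(count + 0.5).  A Monte-Carlo Dirichlet mode (`dirichlet_mc`,
128 instances, seeded) averages clr over draws of Dirichlet(count + 0.5)
per sample, reproducing the behavior of ALDEx2-style estimators; it
converges to the Dirichlet-mean clr as instances grow (checked
stochastically in the tests).  The deterministic mode is the default
because it is reproducible bit-for-bit and the two agree closely at the
read depths involved.

**Temporal ordering.** Each node carries its weighted mean age (WMA): the
mean sampling time of the samples where the ASV is present, weighted by
its relative abundance — a summary of when the ASV peaks, not of when it
first appears.  Because studies sample different time grids, each
network's WMAs are z-scored per network (mean 0, sd 1, n-1 denominator)
into a *scaled WMA*; a network whose WMAs are all equal gets zeros and a
warning.  Force-directed (Fruchterman-Reingold) layouts are computed
seeded, then the x coordinate is replaced by WMA.

## Core network and the rewiring null model

Networks are aligned on the union of their ASV sequences into a
multiplex: one symmetric adjacency layer per study holding the 0-4
support counts, plus node-in-layer presence flags.  For a subset size m,
the intersection distribution lists, for each of the C(L, m) subsets of
layers, the number of vertices present in all m layers or the number of
edges present in all m layers.  The core network with minimum share k
keeps every association found in at least k layers; its node set is the
endpoints of those edges, each positioned at the mean of its per-study
scaled WMA over the layers containing it and annotated with its
prevalence (number of layers containing the ASV).  Note that only ASVs
shared by >= k studies can ever appear in a core at share k, so the core
node set is a subset of the cross-study ASV pool by construction.

**Null model.** Significance of edge sharing is judged by rewiring:
each layer is randomized over its own present nodes, preserving node set
and edge count.  The default is degree-preserving double-edge swaps
(10 x |E| attempted swaps), the stricter null; a `uniform_endpoints`
mode redraws endpoints uniformly (the rewire-with-probability-1 null of
igraph).  Support weights are carried onto the rewired edges in seeded
random order.  For each of `n_sets` = 100 replicate rewired multiplexes,
the observed intersection-size distribution at subset size m is compared
with the replicate's by a two-sided two-sample Kolmogorov-Smirnov test;
the per-replicate p-values and the rejection count at alpha = 0.05 are
reported, separately per m.  Two identically-zero distributions get
p = 1 by convention and are flagged.

**Calibration caveat.** Intersection sizes are small integers, so the KS
test is conservative in the presence of ties, and the 100 comparisons
within one run share the observed sample and are therefore positively
correlated.  The calibration simulation (layers generated by the null
itself, 20 independent outer repeats of 100 comparisons) accordingly
checks that the pooled rejection fraction at alpha = 0.05 falls within
the central 95% band of Binomial(100, 0.05) scaled to a fraction,
[0.01, 0.10] — a band for the *average* level of a correlated, discrete
test, not an independence claim.  The calibration fixture uses 10
structureless Poisson layers so that C(10, 2) = 45 subset sizes spread
over many distinct values, which keeps the discrete KS close to its
nominal level.

## Poisson multiplex SBM

Each ASV i has one latent block label z_i ~ Categorical(pi) shared by all
layers; layer l observes, for each unordered pair present in that layer,
A^l_ij ~ Poisson(lam^l_{z_i z_j}) on the support counts.  Pairs with an
endpoint absent from a layer are treated as *structural zeros* by
default — skipped, not observed zeros — because a study that never
contained an ASV carries no evidence about its associations; a toggle
(`structural_zeros=False`) treats them as observed, since the original
tooling's behavior is not documented.

Inference is mean-field variational EM.  The M-step is closed-form
(pi = column means of tau; lam = tau-weighted pair means per layer and
block pair, floored at 1e-10 for empty block pairs).  The E-step is the
standard log-space fixed-point update with log-sum-exp normalization,
*guarded*: a candidate tau that would decrease the evidence lower bound
(ELBO) is damped halfway toward the previous tau, repeatedly, and
rejected if still decreasing — so the ELBO trace is non-decreasing by
construction (asserted to 1e-8 on every fit in the tests).
Initialization is spectral (k-means on a normalized-Laplacian embedding
of the layer-summed adjacency) plus random-Dirichlet restarts (default
10); the best ELBO wins.  Convergence is a relative ELBO change below
1e-6 (default), capped at 500 iterations.

The number of blocks is chosen by the integrated completed likelihood:
complete-data log-likelihood at the MAP labels minus the Daudin-type
penalty `(1/2) L Q(Q+1)/2 log(N(N-1)/2) + ((Q-1)/2) log N`; the L factor
accounts for layer-specific rate matrices.  The ICL table over the
scanned Q range is retained on the returned fit.

`MultiplexSBM` follows the statsmodels convention: a model object built
from data, `fit(Q)` / `select(Q_range)` returning an `SBMResults` with
`tau`, `pi`, `lam`, `elbo_trace`, `icl`, `labels` and a `summary()`
table.

## Group comparisons

Scaled-WMA and prevalence differences between groups of ASVs (taxonomic
order, SBM cluster, genus, or hetero-/homofermentative type) are tested
with the two-sided Wilcoxon-Mann-Whitney test, pairwise over groups:
exact when n1*n2 <= 400 and tie-free, otherwise normal approximation
with tie and continuity corrections.  Raw p-values are reported with
Benjamini-Hochberg adjusted values alongside.  Comparisons can be run on
core-network nodes or on per-ASV mean scaled WMA across all networks —
both supported because either population is defensible.  The bundled
genus -> fermentation-type TSV classifies obligately heterofermentative
LAB genera as heterofermentative and the rest of the common
fermented-vegetable LAB genera as homofermentative, following the 2020
*Lactobacillaceae* reclassification; it is editable and makes no
completeness claim.

## Synthetic data: what it emulates, and what it does not

The generator plants a three-guild succession with Gaussian-in-time ASV
intensity curves: a diverse early flora (*Pseudomonadales* plus mixed
orders, peak ~1 d, sd 3 d), an *Enterobacterales* bloom (peak ~7 d, sd
6 d), and a *Lactobacillales* community (peak ~30 d, sd 12 d), over 0-60
days.  Base intensities are lognormal with sigma 1.8 — few dominant
ASVs, a long rare tail — and observed counts are Dirichlet-multinomial
(concentration 50 x composition) at lognormal depths with median 30,000
reads (sigma 0.35), giving overdispersed, sparse, compositional tables.
Studies draw shared ASVs from a global pool at per-guild rates
(early 0.85, mid 0.95, late 0.70): the mid guild is the most shared and
the late guild the least, the planted analogue of *Enterobacterales*
being shared more widely than the fermentation-specific LAB.  The rates
are high in absolute terms because with 4 studies and share threshold
k = 3, only widely shared ASVs can form core edges at all; they were
fixed when the generator was designed, with the relative ordering as the
planted biological signal.  The default collection is 4 studies x 40
samples x 6 time points x ~130 ASVs each (~35 shared), sized so the full
pipeline runs in well under two minutes.

Planted multiplexes for the SBM draw labels from pi and pair weights
Poisson(lam) truncated at 4 to stay in the support-count range; the
truncation biases rates downward (E[min(Pois(4), 4)] ~ 3.3), which is why
the rate-recovery test disables it while the label-recovery tests keep
it.

What passing tests show: the pipeline's statistics behave as designed on
data whose generating process matches the model's assumptions (smooth
unimodal temporal niches, exchangeable samples within time points, exact
sequence sharing).  What they do not show: robustness to primer/region
mismatches between studies, compositional artifacts beyond
Dirichlet-multinomial noise, failed fermentations, uneven time grids
biasing WMA, or taxonomic misassignment — all present in real
collections.

## Problem sizes used in the validation suite

Metric oracles: 1,000 random integer vector pairs (5-10 samples).  Null
calibration: 20 repeats x 100 KS comparisons on 10-layer, 100-node
multiplexes with ~495-edge layers.  Planted power: four 70-node layers
sharing a 60-edge common subgraph among 140 edges each.  SBM: N = 60,
L = 4, lam_in = 4, lam_out = 0.2 for label recovery (ARI >= 0.9);
N = 90, L = 3, Q = 3 over 20 seeds for ICL selection; N = 80 without
truncation for rate recovery (median relative error <= 15%).  End to
end: the default 4-study collection.  These sizes keep the whole
validation run in a few minutes on one core while leaving each effect
comfortably detectable.

## Known limitations

* Pairwise metrics over all samples conflate temporal succession with
  association; the networks are descriptive, not causal or conditional
  (no SPIEC-EASI-style deconfounding, by design).
* The KS null test inherits the discreteness and dependence caveats
  above; its rejection counts are comparable across m but its nominal
  level is approximate.
* The SBM likelihood treats support counts (0-4) as unbounded Poisson
  observations; with rates well below 4 the truncation error is
  negligible, but dense layers would violate it.
* WMA compresses a temporal profile to one number; bimodal ASVs (e.g.
  re-blooming taxa) are poorly represented.
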