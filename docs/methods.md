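# Methods

This note documents the models implemented in `soilassembly`, the choices
made where conventions diverge, and what the synthetic benchmarks do and do
not demonstrate.

## Community tables and diversity

Counts are non-negative integers in a sample × taxon matrix; constructing a
`CountTable` drops taxa observed in no sample (with a warning), so occupancy
statistics are always over observable taxa.  Rarefaction is a single
multivariate-hypergeometric draw (subsampling without replacement) to a
fixed depth, deterministic given its seed; samples below the target depth
are dropped with a warning rather than silently kept at unequal effort.
Shannon diversity is reported in nats (natural log).  Bray–Curtis is
computed on rarefied counts; whether one feeds counts, proportions or
transformed abundances is a genuine convention split in the field — counts
after rarefaction is the package's convention, applied uniformly.
"Presence" always means count > 0 after rarefaction.

## Co-occurrence networks

Edges join taxon pairs (within and across kingdoms) with Spearman |ρ| above
a magnitude threshold (default 0.6) *and* a two-sided p below a
significance threshold (default 0.001).  The p-value uses the
t-distribution approximation with average ranks for ties, and no
multiple-testing correction is applied: the dual magnitude + significance
rule is itself the guard against spurious edges, and it makes results
comparable across studies using the same convention.  Isolated nodes are
removed.  Correlations are computed on rarefied counts; because rarefaction
depths are shared within a kingdom, edge sets are invariant to any strictly
monotone transformation of abundances.

A taxon's *niche preference* for an environmental variable is the mean of
that variable over the samples where the taxon is detected, weighted by the
taxon's relative abundance across those samples.  Per-sample *subnetwork
features* come from the subgraph induced on the taxa detected in that
sample: AD = 2E/N, Neg = negative edges / E, Int = bacterium–fungus edges /
E (cross-kingdom edges over all edges, not over candidate pairs).  Samples
whose subnetwork has no edges get AD = Neg = Int = 0 and a `flagged` marker
instead of being dropped, so downstream regressions keep sample alignment.

## βMNTD, βNTI and assembly classification

βMNTD between samples k and m is the abundance-weighted mean distance from
each taxon present in one sample to its nearest phylogenetic neighbour
present in the other (shared taxa contribute zero), averaged over both
directions.  Weights are relative abundances by default (`weighted=False`
gives 1/richness).  Distances are patristic distances on the supplied
rooted tree.

The βNTI null keeps communities fixed and shuffles taxon labels across
**all** tips of the phylogeny — the regional pool, not merely the taxa
observed in the table at hand.  This matters: shuffling within the observed
taxa only re-arranges an already-filtered pool and can erase or even invert
the selection signal.  βNTI is the z-score (observed − null mean)/null sd
with 999 nulls by default (tests use 199; a z-score degrades gracefully
with fewer nulls).  Pairs with zero null standard deviation (e.g. star
phylogenies, or pairs sharing every taxon) are set to NaN with a warning
and excluded from downstream fractions.

Sample pairs are classified as homogeneous selection (βNTI < −2), variable
selection (βNTI > 2) or stochastic (|βNTI| ≤ 2); the boundary value 2 is
stochastic.  Fractions are computed over within-group pairs.  The
fungal-richness analysis ranks samples by richness (ties broken by label
order), splits them into a chosen number of contiguous equal-size groups
(both 14 and 21 are exposed, since the grouping granularity is a free
choice), computes per-group fractions, fits each process fraction against
group mean richness with a degree-2 polynomial, and summarises the
direction as the sign of the fitted derivative averaged over the observed
range.  Finer partitions of stochasticity (dispersal limitation vs drift
via taxonomic null models) are deliberately out of scope.

## Distance decay and driver attribution

Distance–decay regressions fit community similarity (1 − Bray–Curtis) on
great-circle distance (km; a `log10_distance` switch exists because both
conventions are common) by OLS within each habitat group.  Significance
comes from a two-sided Mantel permutation test rather than the parametric
OLS t-test, because the n(n−1)/2 pairwise points are not independent.

The Mantel statistic is the Pearson correlation of the upper triangles
(a Spearman switch exists); the null permutes rows and columns of the
second matrix jointly; p-values use the add-one estimator
(1 + #{r* ≥ r})/(1 + n_perm), one-tailed positive by default.  The partial
Mantel uses the residual method: both triangles are regressed on the
control triangle and the residual of the second matrix is permuted as a
matrix.  If a matrix is entirely explained by the control, the partial
correlation is 0 by convention.

LMG relative importance assigns each predictor the average increase in R²
over all orderings in which it can enter the model, computed by exact
subset enumeration (≤ 12 predictors; shares then sum to the full-model R²
exactly and equal marginal r² in orthogonal designs).  For wider designs a
Monte-Carlo estimator over random orderings is provided; its error shrinks
as 1/√(orderings).  Dominant taxa are those with occupancy strictly above
50% of samples and mean relative abundance in the top 10% of taxa; both
thresholds are parameters.  Per-taxon driver models regress relative
abundance on an abiotic-only and an abiotic+biotic predictor set.  Raw R²
is reported for both (and is necessarily monotone in the predictor set);
the paired one-sided Wilcoxon comparing the two fits uses *adjusted* R²,
which is centred under a null response — on raw R² the test would reject
always, by construction.

Forward-selected distance-based RDA square-root-transforms the Bray–Curtis
matrix (correcting its non-Euclidean geometry), embeds it by principal
coordinates (axes with non-positive eigenvalues discarded), and greedily
adds the standardized driver with the largest gain in explained variance,
admitted while its permutation p ≤ α.  The admission test permutes the
candidate's residuals on the already-selected set (Freedman–Lane), so
shared variance with admitted drivers is not recounted as evidence.

Random-forest importance delegates forest fitting to a standard library;
importance is the mean increase in MSE when a predictor's column is
permuted, expressed as a percentage of Var(y) (a resubstitution-stable
denominator; rankings and p-values are unaffected by this scaling choice).
Significance comes from refitting the forest on response-permuted data,
which accounts for the optimism of fitting importance and null importance
on the same data.

## The synthetic-data generator

The generator is a stand-in: the field systems it emulates are
observational, so the generative model is the package's own construction,
built so that every downstream statistic has a planted truth.

**Phylogeny.** A pure-birth (Yule) tree, rate 1, with pendant edges
extended by the memoryless waiting time to the next speciation so all
branch lengths are positive.

**Environment.** The aridity index AI (1 − precipitation/evapotranspiration)
is uniform on [0.3, 1.0]; twelve edaphic variables and MAT are generated
with fixed correlations to AI (moisture, carbon and nitrogen pools
negative; pH and MAT positive) purely as realistic decorations — assembly
mechanics key on the single AI axis.  Coordinates fall in a 36–41° N,
94–104° E box so geographic distances land in a realistic few-hundred-km
range; habitats are assigned by AI quintile from wetland to desert; two
depth layers alternate; treatments cycle D0…Dk.

**Niche optima.** Taxon optima evolve by Brownian motion along the tree
with an early-burst twist: the step variance on an edge is
rate × length × exp(−8·h), with h the edge's relative height.  Plain
Brownian motion places as much trait variance on terminal branches as on
deep ones, so taxa matching a niche window are phylogenetically scattered
and environmental filtering leaves almost no phylogenetic footprint; the
early-burst decay concentrates divergence on deep splits — strong niche
conservatism — so similar optima mean close relatives, which is the very
assumption that makes βNTI informative.

**Communities.** Expected abundance of taxon i in sample s is a fixed
lognormal metacommunity abundance times exp(−w_s(t_s − o_i)²/(2σ²)), with
σ the niche breadth, t_s the sample's selective target and w_s a selection
weight; counts are multinomial at Poisson-distributed depth, after
multiplicative lognormal noise (cv parameter).  The regimes set (t, w):

- *neutral*: w = 0 — composition independent of tree and environment;
- *homogeneous_filtering*: one shared optimum, w = 1.  The shared optimum
  is chosen among the realised taxon optima so that its kernel supports an
  effective pool of ~15 taxa and that pool is maximally phylogenetically
  compact — selection acting on a conserved trait favours a clade, and the
  planted scenario stays well-posed for every random tree;
- *variable_filtering*: w = 1 with per-sample targets obtained by mapping
  each sample's AI rank onto the quantiles of the realised optima
  ("species sorting"), so targets sweep the whole niche comb regardless of
  where the Brownian realisation put it;
- *richness_coupled*: the shared optimum with w equal to the min–max-scaled
  observed fungal richness of the sample — the fungus-poorest sample
  assembles neutrally, the richest under full selection.

**Fungi.** Treatment level Di retains only the first k_i fungal taxa
(non-increasing k, emulating a fungicide dilution); richness is the tested
variable, not fungicide chemistry.  Fungal depth is configured separately
from bacterial depth (`depth_mean_fungi`), mirroring per-kingdom
rarefaction depths; a shared shallow depth would censor the planted
richness gradient.

**Canonical regime conditions** (`regime_preset`): 100 bacterial taxa,
niche breadth σ = 0.05 AI units, Brownian rate 2.0, noise cv 0.8, mean
bacterial depth 30 reads, fungal depth 1000.  The shallow bacterial depth
is deliberate: at the 100-taxon scale of these benchmarks, which members
of the selected pool a sample realises must be a lottery — that sampling
turnover is what separates homogeneous selection from the null.  (The
`SimConfig` defaults use depth 2000 for general exploration; the presets
are the benchmark conditions.)  Under the presets, the planted process is
the dominant βNTI class in roughly three quarters to five sixths of random
seeds per regime, and the benchmark suite requires 2 of 3 fixed replicate
seeds.

**What passing these benchmarks shows — and does not.** Recovery of
planted regimes shows the estimators have the right sign, calibration and
discriminating power under a known truth with strong niche conservatism
and a univariate gradient.  Real soil data differ in ways the generator
does not emulate: thousands of taxa with far sparser occupancy,
compositional sequencing artefacts, multivariate and interacting
environmental drivers, true biotic interactions (the generator's
co-occurrences arise from shared latent factors or shared niches, not
mechanistic interaction), and phylogenies with topology/branch-length
error.  Results on synthetic data bound what the code does, not what any
particular field system is like.

## Numerical notes

- βNTI is invariant to rescaling all branch lengths (observed and null
  scale together); the implementation is tested for this.
- All permutation tests and simulations take explicit integer seeds; every
  reported quantity is a pure function of (inputs, seed).
- Null standard deviations use the n−1 normalisation over null draws.
- Rank ties everywhere use average ranks; richness-group ties are broken
  by sample label order to keep grouping deterministic.
- Permutation p-values can never be 0 (add-one estimator); a Benjamini–
  Hochberg switch for per-taxon models exists but is off by default, since
  the raw-threshold convention is what makes the networks and models
  comparable with common practice.
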