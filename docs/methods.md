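# Methods

This note documents the models and procedures chronet implements, the
defaults it ships, and the choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design and data model

The package models a tea-plantation chronosequence in which three sites
carry tea stands of different ages (3–90 years) and, at two of the sites,
an adjacent forest representing the pre-conversion land use. Samples are
triplicate plots per stand. Stand ages are binned into four groups used
throughout the network analysis: adjacent forest (`F`), young stands
(`Y3_20`), middle-aged stands (`Y40_50`) and old stands (`Y90`). The bin
edges are configurable (`AgeGroupBins`); the defaults place stands of
≤ 21 years in `Y3_20` and 22–69 years in `Y40_50`, so the observed stand
ages (3, 10, 13, 21, 43, 50, 90) are absorbed without a gap. The 21-year
stand's membership is a judgement call — group naming conventions for it
are inconsistent in field usage — which is why the edges are parameters
rather than constants.

Counts are stored as integers (samples × taxa); relative abundances are
always derived views. Soil chemistry carries pH (water, 1:1), TOC and TON
(g kg⁻¹), C/N, MBC and MBN (mg kg⁻¹), available P and exchangeable K, Ca,
Mg, Na (mg kg⁻¹).

## Synthetic community generator

`simulate_dataset` draws, per sample:

1. a latent Gaussian vector z ~ N(0, Σ_g), where Σ_g is the sample's
   age-group correlation matrix: identity plus within-block constant
   correlation ρ_g for each configured block;
2. expected abundances a_f = exp(μ_f + σ·z_f), i.e. log-normal marginals
   through a Gaussian copula — the copula guarantees a valid joint
   distribution for arbitrary block structure while keeping heavy-tailed
   marginals typical of relative-abundance data;
3. counts ~ Multinomial(depth, a/Σa), with depth uniform on the
   configured range (default 7,265–9,204 reads).

Per-family log-baselines μ_f divide each phylum's weight among its
families (dominant Proteobacteria/Actinobacteria/Acidobacteria by
default) with N(0, 0.3) jitter; the marginal log-sd σ defaults to 1.0,
a moderate within-group dispersion (95% range ≈ 50-fold once baseline
differences are included). Default blocks are three blocks of five
families at ρ = 0.60 (F), 0.75 (Y3_20), 0.85 (Y40_50), 0.92 (Y90) —
a qualitative "associations tighten with stand age" schedule, not a claim
about any particular dataset's effect sizes.

Soil chemistry: TOC = 1.05 + 0.018·age + ε (sd 0.10 g kg⁻¹) and
MBN = 10 + 0.35·age + ε (sd 2.5 mg kg⁻¹), spanning field magnitudes from
forest (age 0) to 90-year stands; pH ~ N(4.1, 0.2) (acidic tea-garden
soils, age-independent); the remaining properties are age-independent
noise around field magnitudes. The truth record stores all within-block
pairs per group and the planted slopes.

Reproducibility: one root `SeedSequence` spawns named substreams
(baselines, depths, soil, one per sample), so per-sample generation order
cannot perturb other streams and equal seeds give byte-identical outputs.

What the generator does **not** emulate: compositional mean shifts between
age groups (group labels carry no Bray–Curtis signal, so PERMANOVA on
default data is a calibration exercise), coupling between soil chemistry
and community composition (forward selection on default data correctly
selects nothing), sequence-level noise, and taxa absent from some
samples (all 60 families are usually present everywhere at depth 7,000).
Passing tests on synthetic data therefore demonstrate correctness of the
estimators and recovery of *planted* structure, not performance on real
communities.

## Rarefaction and diversity

Rarefaction is a single seeded multivariate-hypergeometric draw per sample
(subsampling without replacement to exactly the target depth, default
7,000). A single draw rather than an average over draws keeps counts
integral and downstream results deterministic; samples below the depth are
dropped with a logged warning. Richness is the observed taxon count.
Bray–Curtis d = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) is computed on rarefied counts by
default (at even depth, counts are proportional to relative abundances);
a pair of all-zero samples is an error rather than a silent 0/0.

## Ordination

PCoA double-centers −d²/2 (Gower), eigendecomposes, and scales
eigenvectors by √λ. Bray–Curtis is semi-metric, so negative eigenvalues
occur; they are reported but excluded from coordinates and from the
proportion-explained denominator. No correction is applied by default — a
Lingoes correction is available by option — because db-RDA (below) defines
its own convention.

NMDS minimizes Kruskal stress-1 with SMACOF majorization; disparities come
from pool-adjacent-violators isotonic regression with *weak* (primary) tie
treatment, implemented by ordering tied dissimilarities by current
configuration distance before PAVA. The best of `n_starts` random starts
is returned; the final configuration is centered, rotated to principal
axes and sign-fixed for reproducibility. Non-convergence returns the best
configuration found with `converged=False`.

PCA standardizes columns (optionally) and uses the SVD; component signs
are fixed by making the largest-magnitude loading positive.

## PERMANOVA, db-RDA and forward selection

PERMANOVA uses the direct sums-of-squares decomposition and free label
permutation (the sampling design names no blocking structure); p-values
use the add-one convention (1 + exceedances)/(1 + permutations), which
cannot return zero. `n_permutations="exact"` enumerates every distinct
labeling for small designs. The one-factor test is the default; separate
runs per factor match the reporting convention for this design.
ANOVA is implemented as plain one-way + Tukey: the plots are independent
units per stand, so there is no repeated factor despite the "repeated
measures" label such designs sometimes receive.

db-RDA takes the positive-eigenvalue PCoA axes as the response matrix
(negative axes dropped keeps the constrained proportion interpretable),
z-standardizes explanatory variables — except pH, which is conventionally
left on its own scale (centered only), honoring the "normalize everything
but pH" convention — and tests the pseudo-F by shuffling explanatory rows.

Forward selection uses **double stopping**: a global permutation test of
the full candidate set must reject at α before any stepping occurs; steps
then add the candidate with the smallest marginal permutation p (ties
broken toward larger partial pseudo-F) and stop when the best remaining
p ≥ α. The global gate is essential: per-step minimum-p selection over
~6 candidates has a family-wise false-selection rate near 25% under the
null, while the gated procedure holds it near α (verified by the
calibration tests). Candidates that become collinear with the current
selection are skipped, so duplicated informative variables enter once.

Tukey HSD accepts raw data or published (mean, SD, n) summaries — the
pooled mean square error comes from the per-group variances — and builds
the compact letter display by insert-and-absorb. Zero pooled variance with
unequal means yields all-distinct letters rather than an error.

## Co-occurrence networks

Family-level relative abundances from rarefied counts are correlated with
Spearman's ρ per age group (≥ 4 samples required; constant families
excluded and logged). The abundance scale is a configuration choice —
counts, rarefied counts or relative abundances — because field usage is
inconsistent; rarefied-count relative abundances are the default.
Pair p-values use the t-approximation with n−2 df (the exact-permutation
path in `correlate` is impractical and too granular across ~1,770
simultaneous pairs). Benjamini–Hochberg runs across the upper triangle;
an edge requires |ρ| > 0.8 **and** adjusted p < 0.01 (a flag restores
raw-p thresholding). The magnitude rule uses |ρ|, keeping negative
(co-exclusion) edges as signed edges — dropping them would discard half
the biology the network is meant to show.

Topology (via igraph's C core, with hand-written brute-force oracles in
the tests): average path length and diameter over *reachable pairs only*,
so the statistics stay defined for sparse subnetworks; mean local
clustering with 0 for degree < 2; greedy agglomerative modularity
maximization (deterministic, no random initialization — results are
seed-free); cluster count = communities in that partition; Freeman
betweenness centralization Σ(b_max − bᵢ)/(n−1) with node betweenness
pre-normalized to [0, 1], making the star graph exactly 1. Graphs with
fewer than 2 nodes or no edges report 0 for path-based metrics with a
degenerate flag; modularity of an edgeless graph is reported as 0 in the
topology suite but is an error in `modularity_score`.

Null model: G(n, m) — uniform simple graphs with exactly the observed
node and edge counts (sampled as m distinct pair-indices without
replacement), not G(n, p); "identically sized" comparison requires exact
edge match, and density is then exact for every null graph. The
small-world assessment reports, for average path length, clustering,
cluster count and modularity: the real/null-mean ratio, the empirical
percentile of the real value, and a flag when the real value exceeds the
95th null percentile; the headline small-world call requires clustering
and modularity both above the envelope.

Per-sample subnetworks are induced subgraphs on the families present
(count > 0) in the sample — family-level presence, since the group
networks are family-level objects. Subnetwork parameters are
ln-transformed before Pearson correlation with stand age; parameters
containing zeros use ln(1+x) instead (the transform for zero-valued
parameters is otherwise undefined, and ln(1+x) preserves monotonicity).
Soil correlations use Spearman with soil variables z-normalized except pH
(ranks are unchanged by the scaling; it is kept for reporting
consistency), starred at 0.05/0.01/0.001.

## Numerical conventions

- Permutation p-values: add-one convention everywhere except exact
  enumeration, where p = #{F_perm ≥ F_obs}/#labelings.
- Eigenvalue positivity threshold: λ > 1e-8·max|λ| (PCoA, PCA, db-RDA).
- Statistic comparisons in permutation loops use a 1e-12 slack so exact
  ties count as exceedances.
- Spearman exact p (n ≤ 9 in `correlate`): full enumeration of rank
  permutations, two-sided by |r|.
- BH adjustment: step-up with monotonicity enforcement, capped at 1,
  input order preserved.

## Problem sizes

The test suite and acceptance script run the study-scale design (30
samples × 60 families), 500-replicate null calibrations for PERMANOVA,
200-replicate calibrations for db-RDA, 100-replicate recovery runs for
forward selection and soil trends, 20-replicate network recovery, and a
10,000-graph Erdős–Rényi ensemble at ~100 nodes — the ensemble size the
group-network comparison uses by default.

## Known limitations

- Plain Spearman on compositional data produces closure-induced spurious
  correlations; compositionality-aware estimators (SparCC-style) are out
  of scope by design. At 12 samples per group, the sampling spread of
  Spearman's ρ (sd ≈ 0.06 around a true 0.95-block value) combined with
  BH across 1,770 pairs caps recall of planted edges near 0.6 at the
  |ρ| > 0.8, adjusted-p < 0.01 rule; raw-p thresholding raises recall to
  ≈ 0.87 at the cost of closure-driven false positives (precision
  ≈ 0.86). This trade-off is intrinsic to the edge rule at this sample
  size, not an estimation defect; both modes are exposed.
- Forest groups have 6 samples; at n = 6 the minimum attainable pair
  p-value after BH rarely clears 0.01, so forest networks are typically
  near-empty at default thresholds. Group-level networks at this design
  scale need pooled or larger groups.
- NMDS is a local optimizer; `n_starts` trades time for basin coverage.
- The greedy modularity partition is deterministic but not optimal;
  modularity values are lower bounds on the optimum.
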