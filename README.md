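# chronet

Analysis toolkit for soil bacterial communities sampled along a plantation
chronosequence — a space-for-time series of tea stands of increasing age
plus adjacent forest. It covers the full tabular-to-network path a 16S
amplicon study of this kind needs once an OTU table exists:

- **Diversity**: seeded rarefaction to an even depth, observed richness,
  taxonomic aggregation with a top-*k* + "others" bucket.
- **Ordination**: Bray–Curtis dissimilarity, PCoA (Gower double-centering,
  negative eigenvalues reported, optional Lingoes correction), NMDS
  (Kruskal stress-1 by SMACOF majorization with monotone regression), and
  PCA of soil chemistry.
- **Hypothesis tests**: PERMANOVA (free label permutation, exact
  enumeration for tiny designs), distance-based RDA with permutation
  forward selection of soil variables, one-way ANOVA + Tukey HSD compact
  letter displays (raw data or published mean ± SD summaries),
  Spearman/Pearson correlation with exact small-*n* permutation p, and
  Benjamini–Hochberg adjustment.
- **Co-occurrence networks** (the core): family-level Spearman networks
  thresholded at |ρ| > 0.8 with BH-adjusted p < 0.01, per-sample induced
  subnetworks, a full topology suite (average path length, diameter,
  degree, density, clustering, greedy-modularity partition, Freeman
  betweenness centralization), Erdős–Rényi G(n, m) null ensembles
  (default 10,000 graphs) for small-world assessment, phylum-level link
  summaries, and correlations of subnetwork topology with stand age
  (Pearson on ln-transformed parameters) and soil properties (Spearman).
- **Synthetic communities**: a Gaussian-copula generator that emulates the
  study design (3 sites × {stands, forests} × 3 plots = 30 samples, ~60
  families in 12 phyla, depths 7,265–9,204) with *planted* family–family
  correlation blocks that tighten with stand age and soil trends (TOC and
  MBN increasing with age), plus a machine-readable truth record so every
  downstream stage can be scored against ground truth.

## The statistics at the core

PERMANOVA partitions the squared dissimilarities: with N samples in a
groups, SS_total = Σ_{i<j} d²ᵢⱼ/N, SS_within pools within-group pair sums
scaled by group size, and

    pseudo-F = (SS_between/(a−1)) / (SS_within/(N−a)),  R² = SS_between/SS_total,

with p = (1 + #{F_perm ≥ F_obs}) / (1 + n_permutations) under free label
permutation. db-RDA regresses the positive-eigenvalue PCoA embedding Y on
standardized explanatory variables X; the constrained proportion is
trace(ŶᵀŶ)/trace(YᵀY). A co-occurrence edge joins families a, b when
|ρ_spearman(a, b)| > 0.8 and the BH-adjusted p < 0.01; each group network is
compared against 10,000 uniform random graphs with identical node and edge
counts, and modularity Q = Σ_c [e_c/m − (d_c/2m)²].

## Worked example

```python
import chronet as cn
from chronet import SimulationConfig

# default study design: 30 samples, 10 (site, stand) groups x 3 plots
ds = cn.simulate_dataset(SimulationConfig(seed=1))
rar = cn.rarefy(ds.table, depth=7000, seed=1)
dist = cn.bray_curtis(rar)

res = cn.permanova(dist, ds.samples.frame["age_group"], n_permutations=999, seed=1)
print(f"PERMANOVA age_group: R2={res.R2:.3f} p={res.p_value:.3f}")
# -> PERMANOVA age_group: R2=0.089 p=0.857

# a high-signal single group (latent block correlation 0.95, 12 samples)
cfg = SimulationConfig(seed=1, design={"A": [90]}, plots_per_stand=12,
                       rho_schedule={g: 0.95 for g in ("F", "Y3_20", "Y40_50", "Y90")})
ds2 = cn.simulate_dataset(cfg)
fam = cn.aggregate_by_rank(cn.rarefy(ds2.table, 7000, seed=1),
                           ds2.taxonomy, "family", top_k=None).abundances
rho, p = cn.family_correlations(fam)
net = cn.build_network(rho, p, taxonomy=ds2.taxonomy, abundances=fam, group="Y90")
topo = cn.topology(net)
ens = cn.er_null_ensemble(topo.n_nodes, topo.n_edges, n_graphs=1000, seed=1)
sw = cn.small_world_assessment(topo, ens)
print(f"network: {net.n_nodes} nodes, {net.n_edges} edges; "
      f"clustering ratio vs null {sw.ratios['clustering_coefficient']:.2f}")
# -> network: 13 nodes, 15 edges; clustering ratio vs null 2.88
```

The default-design PERMANOVA is (correctly) non-significant: the generator
plants correlation structure and soil trends, not compositional shifts
between age groups, so group labels carry no Bray–Curtis signal. The
recovered 13-node network sits well above its matched random-graph
ensemble in clustering and modularity — the planted blocks show up as
small-world structure.

A command-line interface mirrors the library:

```bash
chronet simulate --seed 1 --out simulated/
chronet run --seed 1 --out run1/ --depth 7000 --r-threshold 0.8 --null-graphs 10000
chronet report run1/
```

`chronet run` executes the full pipeline (rarefy → aggregate → richness →
Bray–Curtis → PCoA/NMDS → PERMANOVA → db-RDA with forward selection →
group networks → subnetworks → topology → ER nulls → small-world →
topology-vs-age/soil) and writes every artifact plus a manifest with
parameters, derived seeds and SHA-256 checksums; re-running the same
configuration reproduces the checksums bit for bit.

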