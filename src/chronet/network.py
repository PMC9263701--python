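"""Co-occurrence network construction, topology and Erdos-Renyi null models.

Age-group networks are built from pairwise Spearman correlations between
family-level abundances: an edge joins two families when |rho| exceeds the
magnitude threshold (default 0.8) and the Benjamini-Hochberg-adjusted
p-value falls below the significance threshold (default 0.01). Negative
correlations are retained as signed edges. Per-sample subnetworks are the
induced subgraphs on the families present in each sample.

Topology suites (path length, diameter, degree, density, clustering,
greedy-modularity partition, Freeman betweenness centralization) are
computed through igraph's C core; the same suite is evaluated over G(n, m)
Erdos-Renyi ensembles — uniform simple graphs with exactly the observed
node and edge counts — to flag small-world structure (clustering, cluster
count and modularity above the 95th null percentile with comparable path
lengths). Finally, subnetwork topology is correlated with stand age
(Pearson, on ln-transformed parameters) and with soil chemistry (Spearman).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, correlate
from .types import CorrelationNetwork, NetworkTopology, TaxonomyTable, ValidationError

__all__ = [
    "family_correlations",
    "build_network",
    "extract_subnetwork",
    "topology",
    "modularity_score",
    "er_null_ensemble",
    "NullEnsemble",
    "small_world_assessment",
    "SmallWorldAssessment",
    "phylum_link_summary",
    "topology_vs_age",
    "topology_vs_soil",
]

logger = logging.getLogger(__name__)

#: Metrics compared against the null ensemble for the small-world call.
SMALL_WORLD_METRICS = (
    "average_path_length", "clustering_coefficient", "n_clusters", "modularity",
)


# ---------------------------------------------------------------------------
# correlation matrix and thresholded network

def family_correlations(
    abundances: pd.DataFrame, method: str = "spearman"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs correlation among family abundance profiles of one group.

    ``abundances`` is samples x families (counts or relative abundances).
    Families constant across the group's samples are excluded up front (and
    logged): their correlation is undefined. Returns symmetric coefficient
    and raw-p DataFrames over the retained families; p-values use the
    t-approximation with n-2 df.
    """
    n = abundances.shape[0]
    if n < 4:
        raise ValidationError(f"need >= 4 samples for correlations, got {n}")
    x = abundances.to_numpy(dtype=float)
    keep = x.std(axis=0) > 0
    dropped = [str(c) for c, k in zip(abundances.columns, keep) if not k]
    if dropped:
        logger.info("family_correlations: excluding %d constant families: %s",
                    len(dropped), dropped[:10])
    cols = [str(c) for c, k in zip(abundances.columns, keep) if k]
    x = x[:, keep]
    if method == "spearman":
        x = np.apply_along_axis(sps.rankdata, 0, x)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    xc = x - x.mean(axis=0)
    norm = np.sqrt((xc**2).sum(axis=0))
    rho = (xc.T @ xc) / np.outer(norm, norm)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    np.fill_diagonal(p, 0.0)
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def build_network(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    r_threshold: float = 0.8,
    p_threshold: float = 0.01,
    use_fdr: bool = True,
    taxonomy: TaxonomyTable | None = None,
    abundances: pd.DataFrame | None = None,
    group: str | None = None,
    keep_isolated: bool = False,
) -> CorrelationNetwork:
    """Threshold a correlation matrix into a signed co-occurrence network.

    Benjamini-Hochberg adjustment is applied across the upper triangle; an
    edge is kept iff |rho| > ``r_threshold`` and the adjusted p (raw p when
    ``use_fdr=False``) is < ``p_threshold``. Node attributes: family name,
    phylum (via ``taxonomy``), mean relative abundance (via ``abundances``).
    Isolated nodes are dropped unless ``keep_isolated``.
    """
    if list(rho.index) != list(rho.columns) or list(rho.index) != list(p.index) \
            or list(p.index) != list(p.columns):
        raise ValidationError("rho/p matrices must share identical family indices")
    if not (0 < r_threshold < 1):
        raise ValidationError(f"r_threshold must lie in (0, 1), got {r_threshold}")
    families = [str(f) for f in rho.index]
    m = len(families)
    iu = np.triu_indices(m, 1)
    raw = p.to_numpy()[iu]
    adj = bh_adjust(raw) if use_fdr else raw.copy()
    rr = rho.to_numpy()[iu]
    mask = (np.abs(rr) > r_threshold) & (adj < p_threshold)

    phylum = {}
    if taxonomy is not None:
        phylum = taxonomy.rank_series(families, "family").to_dict()
        phylum = {f: taxonomy.rank_of(f, "phylum") for f in families}
    mean_ab = {}
    if abundances is not None:
        rel = abundances.div(abundances.sum(axis=1).replace(0, 1), axis=0)
        mean_ab = rel.reindex(columns=families).mean(axis=0).fillna(0.0).to_dict()

    g = nx.Graph()
    for f in families:
        g.add_node(
            f,
            family=f,
            phylum=str(phylum.get(f, "unclassified")),
            abundance=float(mean_ab.get(f, 0.0)),
        )
    for (i, j, r_val, p_raw, p_adj, ok) in zip(iu[0], iu[1], rr, raw, adj, mask):
        if ok:
            g.add_edge(
                families[i],
                families[j],
                rho=float(r_val),
                p_raw=float(p_raw),
                p_adj=float(p_adj),
                sign="positive" if r_val > 0 else "negative",
            )
    if not keep_isolated:
        g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    return CorrelationNetwork(g, group=group)


def extract_subnetwork(
    network: CorrelationNetwork, sample_abundances: pd.Series
) -> CorrelationNetwork:
    """Induced subgraph on the families present (count > 0) in one sample."""
    present = {str(f) for f, v in sample_abundances.items() if v > 0}
    nodes = [n for n in network.graph.nodes if n in present]
    sub = network.graph.subgraph(nodes).copy()
    return CorrelationNetwork(sub, group=network.group)


# ---------------------------------------------------------------------------
# topology

def _to_igraph(graph: nx.Graph) -> tuple[ig.Graph, list]:
    nodes = list(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in graph.edges()]
    return ig.Graph(n=len(nodes), edges=edges), nodes


def _topology_from_igraph(g: ig.Graph, n_pos: int, n_neg: int) -> NetworkTopology:
    n = g.vcount()
    m = g.ecount()
    degenerate = n < 2 or m == 0
    density = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
    avg_degree = 2.0 * m / n if n > 0 else 0.0

    if m > 0:
        apl = g.average_path_length(unconn=True)  # mean over reachable pairs
        diameter = float(g.diameter(unconn=True))
        local = g.transitivity_local_undirected(mode="zero")
        clustering = float(np.mean(local)) if local else 0.0
        part = g.community_fastgreedy().as_clustering()
        modularity = float(g.modularity(part))
        n_clusters = len(part)
    else:
        apl, diameter, clustering, modularity = 0.0, 0.0, 0.0, 0.0
        n_clusters = n
    if not np.isfinite(apl):
        apl = 0.0

    if n > 2 and m > 0:
        bw = np.asarray(g.betweenness())
        bw = bw / ((n - 1) * (n - 2) / 2.0)
        centralization = float(np.sum(bw.max() - bw) / (n - 1))
    else:
        centralization = 0.0

    return NetworkTopology(
        n_nodes=n,
        n_edges=m,
        n_positive_edges=n_pos,
        n_negative_edges=n_neg,
        average_path_length=float(apl),
        diameter=diameter,
        average_degree=avg_degree,
        graph_density=density,
        clustering_coefficient=clustering,
        modularity=modularity,
        n_clusters=int(n_clusters),
        centralization_betweenness=centralization,
        degenerate=degenerate,
    )


def topology(network: CorrelationNetwork | nx.Graph) -> NetworkTopology:
    """Topological parameter suite of an unweighted, undirected network.

    Average path length and diameter are taken over connected pairs only;
    clustering is the mean local coefficient with 0 for degree < 2;
    modularity and cluster count come from a deterministic greedy
    agglomerative partition; betweenness centralization is the Freeman sum
    with node betweenness normalized to [0, 1]. Graphs with < 2 nodes or no
    edges return 0 for the path-based metrics with ``degenerate=True``.
    """
    graph = network.graph if isinstance(network, CorrelationNetwork) else network
    if graph.number_of_nodes() < 1:
        raise ValidationError("topology needs at least 1 node")
    if isinstance(network, CorrelationNetwork):
        n_pos, n_neg = network.positive_edges(), network.negative_edges()
    else:
        n_pos = sum(1 for _, _, d in graph.edges(data=True)
                    if d.get("sign", "positive") == "positive")
        n_neg = graph.number_of_edges() - n_pos
    g, _ = _to_igraph(graph)
    return _topology_from_igraph(g, n_pos, n_neg)


def modularity_score(network: CorrelationNetwork | nx.Graph, partition) -> float:
    """Newman modularity Q = sum_c [e_c/m - (d_c/2m)^2] of a node partition.

    ``partition`` is an iterable of disjoint node collections covering every
    node. Undefined (error) for edgeless graphs.
    """
    graph = network.graph if isinstance(network, CorrelationNetwork) else network
    m = graph.number_of_edges()
    if m == 0:
        raise ValidationError("modularity undefined for a graph with no edges")
    communities = [set(c) for c in partition]
    seen: set = set()
    for c in communities:
        if c & seen:
            raise ValidationError("partition communities overlap")
        seen |= c
    if seen != set(graph.nodes):
        raise ValidationError("partition does not cover all nodes")
    q = 0.0
    for c in communities:
        e_c = sum(1 for u, v in graph.edges() if u in c and v in c)
        d_c = sum(graph.degree(n) for n in c)
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return q


# ---------------------------------------------------------------------------
# Erdos-Renyi nulls and small-world assessment

@dataclass
class NullEnsemble:
    """Topology distributions over a G(n, m) random-graph ensemble."""

    n_nodes: int
    n_edges: int
    n_graphs: int
    seed: int | None
    metrics: dict[str, np.ndarray]

    def mean(self, metric: str) -> float:
        return float(np.mean(self.metrics[metric]))

    def sd(self, metric: str) -> float:
        return float(np.std(self.metrics[metric], ddof=1))

    def percentile_of(self, metric: str, value: float) -> float:
        """Empirical fraction of null graphs with metric <= value."""
        return float(np.mean(self.metrics[metric] <= value + 1e-12))

    def quantile(self, metric: str, q: float) -> float:
        return float(np.quantile(self.metrics[metric], q))

    def summary(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_graphs": self.n_graphs,
            "metrics": {
                k: {
                    "mean": self.mean(k),
                    "sd": self.sd(k) if self.n_graphs > 1 else 0.0,
                    "p5": self.quantile(k, 0.05),
                    "p95": self.quantile(k, 0.95),
                }
                for k in self.metrics
            },
        }


def _sample_gnm_edges(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    """Uniform sample of m distinct unordered pairs out of C(n, 2)."""
    ncomb = n * (n - 1) // 2
    idx = rng.choice(ncomb, size=m, replace=False)
    # decode linear index -> (i, j), i < j, row-major over the upper triangle
    i = (n - 2 - np.floor(
        np.sqrt(-8.0 * idx + 4.0 * n * (n - 1) - 7) / 2.0 - 0.5
    )).astype(np.int64)
    j = (idx + i + 1 - i * (2 * n - i - 1) // 2).astype(np.int64)
    return np.column_stack([i, j])


def er_null_ensemble(
    n_nodes: int,
    n_edges: int,
    n_graphs: int = 10000,
    seed: int | None = None,
) -> NullEnsemble:
    """Ensemble of uniform G(n, m) graphs with the full topology suite each.

    Every draw is a simple graph with exactly ``n_nodes`` and ``n_edges``
    (density is exact by construction), matching the observed network size.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not (0 <= n_edges <= max_edges):
        raise ValidationError(
            f"impossible edge count {n_edges} for {n_nodes} nodes (max {max_edges})"
        )
    rng = np.random.default_rng(seed)
    keys = (
        "average_path_length", "diameter", "graph_density", "average_degree",
        "clustering_coefficient", "modularity", "n_clusters",
        "centralization_betweenness",
    )
    store = {k: np.empty(n_graphs) for k in keys}
    for t in range(n_graphs):
        edges = _sample_gnm_edges(rng, n_nodes, n_edges)
        g = ig.Graph(n=n_nodes, edges=[tuple(e) for e in edges])
        topo = _topology_from_igraph(g, n_edges, 0)
        d = topo.as_dict()
        for k in keys:
            store[k][t] = d[k]
    return NullEnsemble(
        n_nodes=n_nodes, n_edges=n_edges, n_graphs=n_graphs, seed=seed, metrics=store
    )


@dataclass
class SmallWorldAssessment:
    """Real-vs-null comparison for the small-world call."""

    ratios: dict[str, float]
    percentiles: dict[str, float]
    higher_than_null: dict[str, bool]

    def is_small_world(self) -> bool:
        """Clustering and modular structure above the null envelope."""
        return (
            self.higher_than_null["clustering_coefficient"]
            and self.higher_than_null["modularity"]
        )


def small_world_assessment(
    topo: NetworkTopology, ensemble: NullEnsemble
) -> SmallWorldAssessment:
    """Compare a real network's topology against its matched G(n, m) ensemble.

    For average path length, clustering coefficient, cluster count and
    modularity: ratio of the real value to the null mean, empirical
    percentile of the real value in the ensemble, and a flag set when the
    real value exceeds the 95th null percentile.
    """
    if topo.n_nodes != ensemble.n_nodes or topo.n_edges != ensemble.n_edges:
        raise ValidationError(
            f"ensemble size ({ensemble.n_nodes} nodes, {ensemble.n_edges} edges) "
            f"does not match network ({topo.n_nodes} nodes, {topo.n_edges} edges)"
        )
    d = topo.as_dict()
    ratios, percentiles, flags = {}, {}, {}
    for metric in SMALL_WORLD_METRICS:
        null_mean = ensemble.mean(metric)
        real = float(d[metric])
        ratios[metric] = real / null_mean if null_mean != 0 else np.inf
        percentiles[metric] = ensemble.percentile_of(metric, real)
        flags[metric] = real > ensemble.quantile(metric, 0.95)
    return SmallWorldAssessment(ratios=ratios, percentiles=percentiles, higher_than_null=flags)


# ---------------------------------------------------------------------------
# summaries and trend correlations

def phylum_link_summary(
    network: CorrelationNetwork,
    taxonomy: TaxonomyTable | None = None,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Symmetric phylum x phylum link-count matrix; diagonal = within-phylum.

    Phyla come from node attributes or ``taxonomy``; unmapped nodes count as
    "unclassified". With ``top_k``, phyla outside the top interacting set
    (by total links) are merged into "others".
    """
    def phylum_of(node: str) -> str:
        attr = network.graph.nodes[node].get("phylum")
        if attr:
            return str(attr)
        if taxonomy is not None:
            return taxonomy.rank_of(node, "phylum")
        return "unclassified"

    phyla = sorted({phylum_of(n) for n in network.graph.nodes}) or ["unclassified"]
    mat = pd.DataFrame(0, index=phyla, columns=phyla, dtype=int)
    for u, v in network.graph.edges():
        pu, pv = sorted((phylum_of(u), phylum_of(v)))
        mat.loc[pu, pv] += 1
        if pu != pv:
            mat.loc[pv, pu] += 1
    if top_k is not None and len(phyla) > top_k:
        totals = (mat.sum(axis=1) + np.diag(mat)).sort_values(ascending=False)
        keep = list(totals.index[:top_k])
        drop = [p for p in phyla if p not in keep]
        merged = mat.loc[keep, keep].copy()
        merged["others"] = mat.loc[keep, drop].sum(axis=1)
        others_row = mat.loc[drop, keep].sum(axis=0)
        within_others = int(np.triu(mat.loc[drop, drop].to_numpy()).sum())
        merged.loc["others"] = list(others_row) + [within_others]
        mat = merged
    return mat


def _ln_transform(series: pd.Series) -> pd.Series:
    """ln for strictly positive parameters; ln(1+x) when zeros/negatives occur."""
    if (series > 0).all():
        return np.log(series)
    return np.log1p(series.clip(lower=0))


def topology_vs_age(
    topologies: pd.DataFrame, ages: pd.Series
) -> pd.DataFrame:
    """Pearson correlation of ln-transformed topology parameters with stand age.

    ``topologies`` is samples x parameters (one row per per-sample
    subnetwork); constant parameters are skipped with a warning. Returns a
    frame indexed by parameter with columns ``r`` and ``p``.
    """
    if len(topologies) < 4:
        raise ValidationError("need >= 4 subnetworks for age correlations")
    ages = ages.reindex(topologies.index).astype(float)
    rows = {}
    for param in topologies.columns:
        vals = topologies[param].astype(float)
        if vals.nunique() <= 1:
            logger.warning("topology_vs_age: parameter %r constant, skipped", param)
            continue
        transformed = _ln_transform(vals)
        if transformed.nunique() <= 1:
            logger.warning("topology_vs_age: parameter %r constant after ln, skipped", param)
            continue
        r, p = correlate(transformed.to_numpy(), ages.to_numpy(), method="pearson")
        rows[param] = {"r": r, "p": p}
    return pd.DataFrame(rows).T


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def topology_vs_soil(
    topologies: pd.DataFrame, soil: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Spearman correlations between topology parameters and soil properties.

    Soil variables are z-normalized except pH (kept on its own scale, which
    leaves rank-based coefficients unchanged but matches the reporting
    convention). Returns (rho, p, stars) frames, parameters x soil
    variables, with stars at 0.05/0.01/0.001.
    """
    soil = soil.reindex(topologies.index)
    if len(topologies) < 4:
        raise ValidationError("need >= 4 samples for soil correlations")
    scaled = soil.copy().astype(float)
    for col in scaled.columns:
        if col != "pH":
            sd = scaled[col].std(ddof=1)
            if sd > 0:
                scaled[col] = (scaled[col] - scaled[col].mean()) / sd
    rho = pd.DataFrame(index=topologies.columns, columns=scaled.columns, dtype=float)
    pval = rho.copy()
    for param in topologies.columns:
        tv = topologies[param].astype(float)
        for var in scaled.columns:
            sv = scaled[var]
            if tv.nunique() <= 1 or sv.nunique() <= 1:
                rho.loc[param, var] = np.nan
                pval.loc[param, var] = np.nan
                continue
            r, p = correlate(tv.to_numpy(), sv.to_numpy(), method="spearman")
            rho.loc[param, var] = r
            pval.loc[param, var] = p
    stars = pval.map(lambda p: _stars(p) if np.isfinite(p) else "")
    return rho, pval, stars
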