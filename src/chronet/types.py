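"""Core domain types for chronosequence community analysis.

Everything downstream (diversity, ordination, hypothesis tests, co-occurrence
networks) operates on the small set of validated containers defined here:
an OTU count table, a ranked taxonomy, per-sample metadata joined with soil
chemistry, distance matrices, ordination results, and correlation networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "SOIL_VARIABLES",
    "AGE_GROUPS",
    "AgeGroupBins",
    "OtuTable",
    "TaxonomyTable",
    "SampleTable",
    "DistanceMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "DbRdaResult",
    "TukeyLetters",
    "AggregatedTable",
    "CorrelationNetwork",
    "NetworkTopology",
    "ValidationError",
]

#: Taxonomic ranks, kingdom -> genus, in hierarchical order.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

#: Soil physicochemical variables carried in sample metadata. Units:
#: pH (unitless, water 1:1), TOC/TON g kg^-1, CN ratio (unitless),
#: MBC/MBN/AP/exchangeable cations mg kg^-1.
SOIL_VARIABLES = (
    "pH", "TOC", "TON", "CN", "MBC", "MBN",
    "AP", "ExchK", "ExchCa", "ExchMg", "ExchNa",
)

#: Stand-age groups used for the group-level co-occurrence networks:
#: adjacent forest, young (3-20 y), middle-aged (40-50 y) and old (90 y) stands.
AGE_GROUPS = ("F", "Y3_20", "Y40_50", "Y90")


class ValidationError(ValueError):
    """Raised when an input table or graph violates a container invariant."""


@dataclass(frozen=True)
class AgeGroupBins:
    """Configurable mapping from stand age (years) to age group.

    Forest samples are always ``F`` regardless of age. Tea stands with
    ``stand_age <= young_max`` fall in ``Y3_20``, stands with
    ``young_max < stand_age <= mid_max`` in ``Y40_50``, older stands in
    ``Y90``. Defaults absorb the observed stands (3, 10, 13, 21, 43, 50,
    90 y) into the three tea groups; the 21-year stand's membership is a
    judgement call, hence the bins are configurable rather than hard-coded.
    """

    young_max: float = 21.0
    mid_max: float = 69.0

    def assign(self, stand_age: float | None, land_use: str) -> str:
        if land_use == "forest":
            return "F"
        if stand_age is None or not np.isfinite(stand_age):
            raise ValidationError("tea sample requires a finite stand_age")
        if stand_age <= self.young_max:
            return "Y3_20"
        if stand_age <= self.mid_max:
            return "Y40_50"
        return "Y90"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i, x in enumerate(ids):
        if x in seen:
            raise ValidationError(f"duplicate {what} identifier {x!r} (position {i})")
        seen.add(x)


@dataclass
class OtuTable:
    """Integer count matrix, samples x taxa.

    ``counts`` is a pandas DataFrame indexed by sample id with taxon-id
    columns. ``rarefied_depth`` records the even depth if the table has been
    rarefied, else ``None``. Relative abundances are derived views
    (:meth:`relative_abundance`), never stored.
    """

    counts: pd.DataFrame
    rarefied_depth: int | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        self.counts.index.name = None
        self.counts.columns.name = None
        _check_unique(list(self.counts.index), "sample")
        _check_unique(list(self.counts.columns), "taxon")
        values = self.counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.integer):
                fractional = np.mod(values, 1) != 0
                if np.any(fractional):
                    i, j = np.argwhere(fractional)[0]
                    raise ValidationError(
                        "non-integer count at sample "
                        f"{self.counts.index[i]!r}, taxon {self.counts.columns[j]!r}"
                    )
                self.counts = self.counts.astype(np.int64)
                values = self.counts.to_numpy()
            if np.any(values < 0):
                i, j = np.argwhere(values < 0)[0]
                raise ValidationError(
                    "negative count at sample "
                    f"{self.counts.index[i]!r}, taxon {self.counts.columns[j]!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalized counts; all-zero samples stay all-zero."""
        totals = self.counts.sum(axis=1).astype(float)
        totals[totals == 0] = 1.0
        return self.counts.div(totals, axis=0)


@dataclass
class TaxonomyTable:
    """Per-taxon ranked lineage (kingdom..genus); missing ranks are "unclassified"."""

    lineages: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.lineages, pd.DataFrame):
            self.lineages = pd.DataFrame(self.lineages)
        _check_unique(list(self.lineages.index), "taxon")
        for rank in RANKS:
            if rank not in self.lineages.columns:
                self.lineages[rank] = "unclassified"
        self.lineages = self.lineages[list(RANKS)].fillna("unclassified").astype(str)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.lineages.index)

    def rank_of(self, taxon_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
        if taxon_id not in self.lineages.index:
            return "unclassified"
        return str(self.lineages.at[taxon_id, rank])

    def rank_series(self, taxa: Iterable[str], rank: str) -> pd.Series:
        """Rank value per requested taxon; taxa absent from the table map to "unclassified"."""
        if rank not in RANKS:
            raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
        taxa = list(taxa)
        out = self.lineages[rank].reindex(taxa).fillna("unclassified")
        out.index = taxa
        return out


@dataclass
class SampleTable:
    """Per-sample metadata (site, stand age, land use, plot, age group) + soil chemistry.

    ``frame`` is indexed by sample id with columns ``site``, ``stand_age``
    (NaN for forest), ``land_use`` in {tea, forest}, ``plot``, ``age_group``
    in :data:`AGE_GROUPS`, plus the :data:`SOIL_VARIABLES` present.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.frame.index), "sample")
        f = self.frame
        for col in ("site", "land_use", "age_group"):
            if col not in f.columns:
                raise ValidationError(f"sample table missing column {col!r}")
        bad_use = set(f["land_use"]) - {"tea", "forest"}
        if bad_use:
            raise ValidationError(f"unknown land_use values {sorted(bad_use)}")
        bad_group = set(f["age_group"]) - set(AGE_GROUPS)
        if bad_group:
            raise ValidationError(f"unknown age_group values {sorted(bad_group)}")
        forest = f["land_use"] == "forest"
        if not (forest == (f["age_group"] == "F")).all():
            raise ValidationError("land_use=forest must coincide exactly with age_group=F")
        if "pH" in f.columns:
            ph = f["pH"].astype(float)
            if ((ph <= 0) | (ph >= 14)).any():
                offender = f.index[(ph <= 0) | (ph >= 14)][0]
                raise ValidationError(f"pH outside (0, 14) for sample {offender!r}")
        for col in SOIL_VARIABLES:
            if col == "pH" or col not in f.columns:
                continue
            vals = f[col].astype(float)
            if (vals < 0).any():
                offender = f.index[vals < 0][0]
                raise ValidationError(f"negative {col} for sample {offender!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def soil(self) -> pd.DataFrame:
        cols = [c for c in SOIL_VARIABLES if c in self.frame.columns]
        return self.frame[cols].astype(float)

    def ages(self) -> pd.Series:
        """Stand age with forest coded as 0 years (land use prior to planting)."""
        return self.frame["stand_age"].astype(float).fillna(0.0)


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        _check_unique(self.ids, "sample")
        if self.values.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {self.values.shape} does not match {n} ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if np.any(self.values < -1e-12):
            raise ValidationError("negative dissimilarity")
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class OrdinationResult:
    """Embedding of samples produced by PCoA, NMDS, PCA or db-RDA.

    ``coordinates`` is samples x axes. Eigen-based methods carry
    ``eigenvalues`` (full spectrum, negatives included for PCoA) and
    ``proportion_explained`` over the positive part; NMDS carries ``stress``
    (Kruskal stress-1) and a convergence flag instead.
    """

    method: str
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray | None = None
    proportion_explained: np.ndarray | None = None
    stress: float | None = None
    converged: bool = True
    loadings: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.proportion_explained is not None:
            p = np.asarray(self.proportion_explained, dtype=float)
            if p.size and (np.any(np.diff(p) > 1e-9) or p.sum() > 1 + 1e-9):
                raise ValidationError(
                    "proportion explained must be non-increasing and sum to <= 1"
                )


@dataclass
class PermanovaResult:
    """Pseudo-F partition of distance-matrix variance between group labels."""

    factor: str
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.R2 <= 1.0 + 1e-12):
            raise ValidationError(f"R2 {self.R2} outside [0, 1]")
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside (0, 1]")


@dataclass
class DbRdaResult:
    """Distance-based RDA summary: constrained fraction and permutation test."""

    constrained_proportion: float
    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    pseudo_F: float
    p_value: float
    n_permutations: int
    variables: list[str]
    coordinates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.constrained_proportion <= 1.0 + 1e-9):
            raise ValidationError(
                f"constrained proportion {self.constrained_proportion} outside [0, 1]"
            )


@dataclass
class TukeyLetters:
    """Compact letter display: groups sharing a letter are not separable at alpha."""

    letters: dict[str, str]
    alpha: float
    anova_F: float | None = None
    anova_p: float | None = None


@dataclass
class AggregatedTable:
    """Relative abundances aggregated to a taxonomic rank, with optional "others" bucket."""

    abundances: pd.DataFrame
    rank: str
    has_others: bool

    def __post_init__(self) -> None:
        rows = self.abundances.sum(axis=1)
        nonzero = rows[rows > 0]
        if len(nonzero) and not np.allclose(nonzero, 1.0, atol=1e-9):
            raise ValidationError("aggregated rows must sum to 1")


class CorrelationNetwork:
    """Signed co-occurrence network over family taxa.

    Thin wrapper around an undirected :class:`networkx.Graph`. Nodes are
    family names with attributes ``family``, ``phylum`` and ``abundance``
    (mean relative abundance); edges carry ``rho``, ``p_raw``, ``p_adj`` and
    ``sign`` in {positive, negative}. ``group`` labels the age group the
    network was built from.
    """

    def __init__(self, graph: nx.Graph | None = None, group: str | None = None):
        self.graph = graph if graph is not None else nx.Graph()
        self.group = group
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValidationError(f"self-edge on node {u!r}")
            if "sign" in data and data["sign"] not in ("positive", "negative"):
                raise ValidationError(f"bad edge sign {data['sign']!r} on {u!r}-{v!r}")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[tuple[str, str]]:
        return {tuple(sorted((u, v))) for u, v in self.graph.edges()}

    def positive_edges(self) -> int:
        return sum(1 for _, _, d in self.graph.edges(data=True)
                   if d.get("sign", "positive") == "positive")

    def negative_edges(self) -> int:
        return self.n_edges - self.positive_edges()


@dataclass
class NetworkTopology:
    """Topological parameter vector of an (unweighted, undirected) network.

    Path-based statistics (average path length, diameter) are computed over
    connected pairs only, so they stay defined for disconnected subnetworks.
    ``degenerate`` flags graphs too small for path-based metrics (< 2 nodes
    or no edges).
    """

    n_nodes: int
    n_edges: int
    n_positive_edges: int
    n_negative_edges: int
    average_path_length: float
    diameter: float
    average_degree: float
    graph_density: float
    clustering_coefficient: float
    modularity: float
    n_clusters: int
    centralization_betweenness: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.graph_density <= 1 + 1e-12):
            raise ValidationError(f"density {self.graph_density} outside [0, 1]")
        if self.n_edges != self.n_positive_edges + self.n_negative_edges:
            raise ValidationError("edge sign counts do not sum to edge count")
        if self.n_nodes > 0:
            expected = 2.0 * self.n_edges / self.n_nodes
            if abs(self.average_degree - expected) > 1e-9:
                raise ValidationError("average degree inconsistent with edge count")

    def as_dict(self) -> dict[str, float]:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_positive_edges": self.n_positive_edges,
            "n_negative_edges": self.n_negative_edges,
            "average_path_length": self.average_path_length,
            "diameter": self.diameter,
            "average_degree": self.average_degree,
            "graph_density": self.graph_density,
            "clustering_coefficient": self.clustering_coefficient,
            "modularity": self.modularity,
            "n_clusters": self.n_clusters,
            "centralization_betweenness": self.centralization_betweenness,
            "degenerate": bool(self.degenerate),
        }
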