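"""Rarefaction, richness, rank aggregation and Bray-Curtis dissimilarity."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .types import AggregatedTable, DistanceMatrix, OtuTable, TaxonomyTable, ValidationError

__all__ = ["rarefy", "observed_richness", "aggregate_by_rank", "bray_curtis"]

logger = logging.getLogger(__name__)


def rarefy(table: OtuTable, depth: int = 7000, seed: int | None = None) -> OtuTable:
    """Subsample every sample without replacement to an even ``depth``.

    Samples whose total falls below ``depth`` are dropped with a logged
    warning. The draw is a single seeded multivariate hypergeometric per
    sample (one realization, not an average over draws), so every rarefied
    total equals ``depth`` exactly and downstream results are deterministic
    given the seed.
    """
    if depth <= 0:
        raise ValidationError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals[totals >= depth].index
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if dropped:
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s", len(dropped), depth, dropped
        )
    out = np.empty((len(keep), table.n_taxa), dtype=np.int64)
    for i, sample in enumerate(keep):
        row = table.counts.loc[sample].to_numpy()
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    rarefied = OtuTable(
        pd.DataFrame(out, index=list(keep), columns=table.taxon_ids),
        rarefied_depth=depth,
    )
    return rarefied


def observed_richness(table: OtuTable) -> pd.Series:
    """Observed taxon richness: number of taxa with count > 0 per sample."""
    return (table.counts > 0).sum(axis=1).rename("richness")


def aggregate_by_rank(
    table: OtuTable,
    taxonomy: TaxonomyTable,
    rank: str = "phylum",
    top_k: int | None = 10,
) -> AggregatedTable:
    """Sum counts by rank value and convert to relative abundance.

    Categories outside the ``top_k`` by mean relative abundance are merged
    into ``"others"``; the ``"unclassified"`` category is kept on its own and
    does not compete for a top-k slot. ``top_k=None`` disables bucketing.
    """
    labels = taxonomy.rank_series(table.taxon_ids, rank)
    grouped = table.counts.T.groupby(labels.values).sum().T
    rel = grouped.div(grouped.sum(axis=1).replace(0, 1), axis=0)

    has_others = False
    if top_k is not None:
        named = [c for c in rel.columns if c != "unclassified"]
        order = rel[named].mean(axis=0).sort_values(ascending=False)
        keep = list(order.index[:top_k])
        drop = [c for c in named if c not in keep]
        if drop:
            others = rel[drop].sum(axis=1)
            rel = rel[keep + (["unclassified"] if "unclassified" in rel.columns else [])]
            rel = rel.copy()
            rel["others"] = others
            has_others = True
        else:
            cols = keep + (["unclassified"] if "unclassified" in rel.columns else [])
            rel = rel[cols]
    return AggregatedTable(abundances=rel, rank=rank, has_others=has_others)


def bray_curtis(data: OtuTable | pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, d = sum|x-y| / sum(x+y).

    Accepts raw/rarefied counts or relative abundances (the statistic is
    scale-invariant per pair at even depth). A pair of all-zero samples has
    no defined dissimilarity and raises.
    """
    df = data.counts if isinstance(data, OtuTable) else data
    if df.shape[0] < 2:
        raise ValidationError("Bray-Curtis needs at least 2 samples")
    x = df.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValidationError("Bray-Curtis requires non-negative values")
    zero_rows = np.where(x.sum(axis=1) == 0)[0]
    if len(zero_rows) >= 2:
        ids = [df.index[i] for i in zero_rows]
        raise ValidationError(f"Bray-Curtis undefined between all-zero samples: {ids}")
    condensed = pdist(x, metric="braycurtis")
    return DistanceMatrix(ids=list(df.index), values=squareform(condensed))
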