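"""Readers and writers for tabular and graph artifacts.

All tables are UTF-8 tab-separated text; networks go to GraphML/GEXF
(Gephi-compatible) or a flat edge-list TSV; result records to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd

from .types import (
    RANKS,
    SOIL_VARIABLES,
    AgeGroupBins,
    CorrelationNetwork,
    OtuTable,
    SampleTable,
    TaxonomyTable,
    ValidationError,
)

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_sample_table",
    "write_sample_table",
    "read_network",
    "write_network",
    "write_json",
    "read_json",
]

_TAXONOMY_COLUMN_NAMES = {"taxonomy", "consensus lineage", "consensuslineage", "lineage"}


def _split_lineage(lineage: str) -> dict[str, str]:
    """Split a semicolon lineage, tolerating QIIME-style ``k__``/``p__`` prefixes."""
    parts = [p.strip() for p in str(lineage).split(";")]
    out: dict[str, str] = {}
    for rank, part in zip(RANKS, parts):
        if "__" in part:
            part = part.split("__", 1)[1]
        out[rank] = part if part else "unclassified"
    return out


def read_otu_table(
    path: str | Path,
    orientation: str = "auto",
    sample_ids: list[str] | None = None,
) -> OtuTable:
    """Read a classic tab-separated OTU table.

    The first column holds identifiers; ``orientation`` is one of
    ``samples_as_rows``, ``taxa_as_rows`` or ``auto``. Auto-detection
    matches identifiers against ``sample_ids`` when given, otherwise the
    header sentinel ``#OTU ID`` (taxa as rows) is honored and the fallback
    is samples-as-rows. A trailing taxonomy column, if present, is split
    off into a :class:`TaxonomyTable` attached as ``table.taxonomy``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None, dtype=str)
    df.index = df.index.astype(str)

    taxonomy = None
    tax_cols = [c for c in df.columns if str(c).strip().lower() in _TAXONOMY_COLUMN_NAMES]
    if tax_cols:
        lineages = df[tax_cols[0]]
        df = df.drop(columns=tax_cols)
        taxonomy = TaxonomyTable(
            pd.DataFrame([_split_lineage(x) for x in lineages], index=lineages.index)
        )

    try:
        counts = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path.name}: non-numeric count entry ({exc})") from exc

    if orientation == "auto":
        if sample_ids is not None:
            in_header = len(set(map(str, sample_ids)) & set(map(str, df.columns)))
            in_index = len(set(map(str, sample_ids)) & set(map(str, df.index)))
            orientation = "taxa_as_rows" if in_header >= in_index else "samples_as_rows"
        elif str(df.index.name or "").lstrip("#").strip().lower() in {"otu id", "otu_id", "otu"}:
            orientation = "taxa_as_rows"
        else:
            orientation = "samples_as_rows"
    if orientation == "taxa_as_rows":
        counts = counts.T
        if taxonomy is None:
            pass
    elif orientation != "samples_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    frac = np.mod(counts.to_numpy(), 1) != 0
    if frac.any():
        i, j = np.argwhere(frac)[0]
        raise ValidationError(
            f"{path.name}: non-integer count at row {counts.index[i]!r}, "
            f"column {counts.columns[j]!r}"
        )
    neg = counts.to_numpy() < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValidationError(
            f"{path.name}: negative count at row {counts.index[i]!r}, "
            f"column {counts.columns[j]!r}"
        )
    table = OtuTable(counts.astype(np.int64))
    table.taxonomy = taxonomy  # type: ignore[attr-defined]
    return table


def write_otu_table(table: OtuTable, path: str | Path, orientation: str = "samples_as_rows") -> None:
    path = Path(path)
    df = table.counts
    if orientation == "taxa_as_rows":
        df = df.T
        df.index.name = "#OTU ID"
    elif orientation == "samples_as_rows":
        df = df.copy()
        df.index.name = "sample_id"
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = [c.lower() for c in df.columns]
    return TaxonomyTable(df)


def write_taxonomy(taxonomy: TaxonomyTable, path: str | Path) -> None:
    out = taxonomy.lineages.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_sample_table(
    metadata_path: str | Path,
    soil_path: str | Path | None = None,
    bins: AgeGroupBins | None = None,
    otu_sample_ids: list[str] | None = None,
) -> SampleTable:
    """Read per-sample metadata, join soil chemistry, derive age groups.

    ``metadata_path`` needs columns sample_id, site, stand_age (blank for
    forest), land_use, plot; ``soil_path`` holds sample_id plus any of the
    soil variables. Age group is derived from stand age / land use via
    ``bins`` (defaults: Y3_20 <= 21 y < Y40_50 <= 69 y < Y90).
    """
    bins = bins or AgeGroupBins()
    meta = pd.read_csv(metadata_path, sep="\t", index_col="sample_id", dtype=str)
    meta.index = meta.index.astype(str)
    meta["stand_age"] = pd.to_numeric(meta.get("stand_age"), errors="coerce")
    if soil_path is not None:
        soil = pd.read_csv(soil_path, sep="\t", index_col="sample_id")
        soil.index = soil.index.astype(str)
        missing = sorted(set(meta.index) ^ set(soil.index))
        if missing:
            raise ValidationError(
                f"metadata/soil sample ids do not match; offenders: {missing}"
            )
        meta = meta.join(soil[[c for c in soil.columns if c in SOIL_VARIABLES]])
    if otu_sample_ids is not None:
        missing = sorted(set(otu_sample_ids) ^ set(meta.index))
        if missing:
            raise ValidationError(
                f"metadata sample ids do not match OTU table; offenders: {missing}"
            )
    meta["age_group"] = [
        bins.assign(age if np.isfinite(age) else None, use)
        for age, use in zip(meta["stand_age"].astype(float), meta["land_use"])
    ]
    return SampleTable(meta)


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    out = samples.frame.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def write_network(network: CorrelationNetwork, path: str | Path, format: str = "graphml") -> None:
    """Export a correlation network; an empty network yields a valid empty file.

    Formats: ``graphml``, ``gexf`` (both Gephi-readable), or ``edgelist``
    (TSV with columns source, target, rho, p_raw, p_adj, sign).
    """
    path = Path(path)
    fmt = format.lower()
    g = network.graph.copy()
    if network.group is not None:
        g.graph["group"] = network.group
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "gexf":
        nx.write_gexf(g, path)
    elif fmt in ("edgelist", "tsv"):
        rows = [
            {
                "source": u, "target": v,
                "rho": d.get("rho", np.nan),
                "p_raw": d.get("p_raw", np.nan),
                "p_adj": d.get("p_adj", np.nan),
                "sign": d.get("sign", ""),
            }
            for u, v, d in g.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "rho", "p_raw", "p_adj", "sign"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "graphml") -> CorrelationNetwork:
    path = Path(path)
    fmt = format.lower()
    if fmt == "graphml":
        g = nx.read_graphml(path)
    elif fmt == "gexf":
        g = nx.read_gexf(path)
        g = nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
    else:
        raise ValueError(f"unknown network format {format!r} for reading")
    group = g.graph.get("group")
    return CorrelationNetwork(nx.Graph(g), group=group)


def write_json(obj: Any, path: str | Path) -> None:
    def _default(x: Any) -> Any:
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, (set, frozenset)):
            return sorted(x)
        raise TypeError(f"not JSON serializable: {type(x)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default, sort_keys=True))


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())
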