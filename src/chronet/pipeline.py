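"""End-to-end chronosequence analysis pipeline.

Runs rarefaction -> aggregation -> richness -> Bray-Curtis -> PCoA/NMDS ->
PERMANOVA -> db-RDA with forward selection -> per-age-group co-occurrence
networks -> per-sample subnetworks -> topology -> Erdos-Renyi nulls ->
small-world assessment -> topology-vs-age/soil correlations, writing every
artifact plus a machine-readable manifest (parameters, seeds, checksums).
Any stage failure aborts with the stage name; partial outputs are retained
next to a FAILED marker.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .diversity import aggregate_by_rank, bray_curtis, observed_richness, rarefy
from .network import (
    build_network,
    er_null_ensemble,
    extract_subnetwork,
    family_correlations,
    phylum_link_summary,
    small_world_assessment,
    topology,
    topology_vs_age,
    topology_vs_soil,
)
from .ordination import nmds, pcoa
from .simulate import SimulationConfig, simulate_dataset
from .stats import dbrda, forward_select, permanova
from .types import AGE_GROUPS, AgeGroupBins, SOIL_VARIABLES, ValidationError

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class PipelineConfig:
    """Pipeline parameters; either input paths or ``simulate=True``."""

    out_dir: str = "chronet_out"
    seed: int = 0
    simulate: bool = True
    simulation: SimulationConfig | None = None
    otu_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    soil_path: str | None = None
    depth: int = 7000
    r_threshold: float = 0.8
    p_threshold: float = 0.01
    use_fdr: bool = True
    n_permutations: int = 999
    null_graphs: int = 10000
    min_group_samples: int = 4
    bins: AgeGroupBins = field(default_factory=AgeGroupBins)
    run_dbrda: bool = True
    nmds_starts: int = 8

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        raw = yaml.safe_load(open(path)) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = SimulationConfig(**raw["simulation"])
        if "bins" in raw and isinstance(raw["bins"], dict):
            raw["bins"] = AgeGroupBins(**raw["bins"])
        return cls(**raw)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str, out: Path):
    """Context translating any stage exception into a PipelineError + marker."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                (out / "FAILED").write_text(f"stage {name}: {exc}\n")
                raise PipelineError(name, str(exc)) from exc
            logger.info("stage %s: done", name)
            return False
    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": [], "parameters": {
        "seed": config.seed, "depth": config.depth,
        "r_threshold": config.r_threshold, "p_threshold": config.p_threshold,
        "use_fdr": config.use_fdr, "n_permutations": config.n_permutations,
        "null_graphs": config.null_graphs,
        "bins": {"young_max": config.bins.young_max, "mid_max": config.bins.mid_max},
    }}
    root = np.random.SeedSequence(config.seed)
    sub = {name: int(s.generate_state(1)[0] % (2**31))
           for name, s in zip(
               ("rarefy", "nmds", "permanova", "dbrda", "forward", "nulls"),
               root.spawn(6))}
    report["parameters"]["substream_seeds"] = sub

    with _stage("load", out):
        if config.simulate:
            sim_cfg = config.simulation or SimulationConfig(seed=config.seed)
            dataset = simulate_dataset(sim_cfg)
            table, taxonomy, samples = dataset.table, dataset.taxonomy, dataset.samples
            cio.write_json(dataset.truth, out / "truth.json")
        else:
            if not (config.otu_path and config.metadata_path):
                raise ValidationError("need otu_path and metadata_path when simulate=False")
            table = cio.read_otu_table(config.otu_path)
            taxonomy = (cio.read_taxonomy(config.taxonomy_path)
                        if config.taxonomy_path
                        else getattr(table, "taxonomy", None))
            if taxonomy is None:
                raise ValidationError("no taxonomy provided (file or embedded column)")
            samples = cio.read_sample_table(
                config.metadata_path, config.soil_path, bins=config.bins,
                otu_sample_ids=table.sample_ids,
            )
        cio.write_otu_table(table, out / "otu_table.tsv")
        cio.write_taxonomy(taxonomy, out / "taxonomy.tsv")
        cio.write_sample_table(samples, out / "samples.tsv")
        logger.info("loaded %d samples x %d taxa", table.n_samples, table.n_taxa)

    with _stage("rarefy", out):
        rarefied = rarefy(table, depth=config.depth, seed=sub["rarefy"])
        cio.write_otu_table(rarefied, out / "otu_rarefied.tsv")
        samples = type(samples)(samples.frame.loc[rarefied.sample_ids])
        report["n_samples"] = rarefied.n_samples

    with _stage("richness", out):
        richness = observed_richness(rarefied)
        richness.to_csv(out / "richness.tsv", sep="\t")

    with _stage("aggregate", out):
        phylum_table = aggregate_by_rank(rarefied, taxonomy, "phylum", top_k=10)
        phylum_table.abundances.to_csv(out / "phylum_abundance.tsv", sep="\t")
        family_table = aggregate_by_rank(rarefied, taxonomy, "family", top_k=None)

    with _stage("distances", out):
        dist = bray_curtis(rarefied)
        dist.to_frame().to_csv(out / "braycurtis.tsv", sep="\t")

    with _stage("ordination", out):
        pc = pcoa(dist)
        pc.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
        cio.write_json(
            {"eigenvalues": pc.eigenvalues, "proportion_explained": pc.proportion_explained},
            out / "pcoa.json",
        )
        nm = nmds(dist, seed=sub["nmds"], n_starts=config.nmds_starts)
        nm.coordinates.to_csv(out / "nmds_coordinates.tsv", sep="\t")
        cio.write_json({"stress": nm.stress, "converged": nm.converged}, out / "nmds.json")
        report["pcoa_axis_proportions"] = [float(x) for x in pc.proportion_explained[:2]]
        report["nmds_stress"] = float(nm.stress)

    with _stage("permanova", out):
        perm_results = {}
        for factor in ("age_group", "site"):
            labels = samples.frame[factor]
            res = permanova(
                dist, labels, n_permutations=config.n_permutations,
                seed=sub["permanova"], factor=factor,
            )
            perm_results[factor] = {
                "pseudo_F": res.pseudo_F, "R2": res.R2, "p_value": res.p_value,
                "n_permutations": res.n_permutations,
            }
        cio.write_json(perm_results, out / "permanova.json")
        report["permanova"] = perm_results

    if config.run_dbrda:
        with _stage("dbrda", out):
            soil = samples.soil()
            if soil.shape[1] == 0:
                raise ValidationError("db-RDA requested but no soil properties available")
            selected = forward_select(
                dist, soil, alpha=0.05,
                n_permutations=min(config.n_permutations, 499), seed=sub["forward"],
            )
            chosen = [s.variable for s in selected] or list(soil.columns)
            rda = dbrda(
                dist, soil[chosen], n_permutations=config.n_permutations, seed=sub["dbrda"],
            )
            cio.write_json(
                {
                    "selected": [
                        {"variable": s.variable, "pseudo_F": s.pseudo_F, "p": s.p_value}
                        for s in selected
                    ],
                    "constrained_proportion": rda.constrained_proportion,
                    "pseudo_F": rda.pseudo_F,
                    "p_value": rda.p_value,
                },
                out / "dbrda.json",
            )
            report["dbrda"] = {
                "selected": [s.variable for s in selected],
                "constrained_proportion": rda.constrained_proportion,
                "p_value": rda.p_value,
            }

    with _stage("networks", out):
        fam_rel = family_table.abundances
        networks = {}
        group_sizes = {}
        for group in AGE_GROUPS:
            members = samples.frame.index[samples.frame["age_group"] == group]
            group_sizes[group] = len(members)
            if len(members) < config.min_group_samples:
                logger.warning("group %s: %d samples < %d, skipping network",
                               group, len(members), config.min_group_samples)
                continue
            rho, p = family_correlations(fam_rel.loc[members])
            net = build_network(
                rho, p, r_threshold=config.r_threshold,
                p_threshold=config.p_threshold, use_fdr=config.use_fdr,
                taxonomy=taxonomy, abundances=fam_rel.loc[members], group=group,
            )
            networks[group] = net
            cio.write_network(net, out / f"network_{group}.graphml", "graphml")
            cio.write_network(net, out / f"network_{group}.tsv", "edgelist")
            phylum_link_summary(net).to_csv(out / f"phylum_links_{group}.tsv", sep="\t")
            logger.info("group %s: %d nodes, %d edges", group, net.n_nodes, net.n_edges)
        report["network_edges"] = {g: n.n_edges for g, n in networks.items()}
        report["group_sizes"] = group_sizes

    with _stage("topology", out):
        topo_rows = {}
        for group, net in networks.items():
            if net.n_nodes == 0:
                continue
            topo_rows[group] = topology(net).as_dict()
        topo_frame = pd.DataFrame(topo_rows).T
        topo_frame.to_csv(out / "group_topology.tsv", sep="\t")
        report["group_topology"] = topo_rows

    with _stage("subnetworks", out):
        sub_rows = {}
        for group, net in networks.items():
            members = samples.frame.index[samples.frame["age_group"] == group]
            for sample in members:
                subnet = extract_subnetwork(net, rarefied.counts.loc[sample])
                if subnet.n_nodes == 0:
                    continue
                sub_rows[sample] = topology(subnet).as_dict()
        sub_topo = pd.DataFrame(sub_rows).T
        sub_topo.to_csv(out / "subnetwork_topology.tsv", sep="\t")

    with _stage("nulls", out):
        null_summaries = {}
        small_world = {}
        for group, net in networks.items():
            if net.n_nodes < 3 or net.n_edges < 1:
                continue
            ens = er_null_ensemble(
                net.n_nodes, net.n_edges, n_graphs=config.null_graphs,
                seed=sub["nulls"],
            )
            null_summaries[group] = ens.summary()
            sw = small_world_assessment(topology(net), ens)
            small_world[group] = {
                "ratios": sw.ratios,
                "percentiles": sw.percentiles,
                "higher_than_null": sw.higher_than_null,
                "is_small_world": sw.is_small_world(),
            }
        cio.write_json(null_summaries, out / "null_ensembles.json")
        cio.write_json(small_world, out / "small_world.json")
        report["small_world"] = {
            g: d["is_small_world"] for g, d in small_world.items()
        }

    with _stage("trends", out):
        if len(sub_topo) >= 4:
            params = ["average_path_length", "centralization_betweenness",
                      "n_edges", "n_nodes"]
            present = [p for p in params if p in sub_topo.columns]
            ages = samples.ages().reindex(sub_topo.index)
            tea = samples.frame.reindex(sub_topo.index)["land_use"] == "tea"
            vs_age = topology_vs_age(sub_topo.loc[tea, present], ages[tea]) \
                if tea.sum() >= 4 else pd.DataFrame(columns=["r", "p"])
            vs_age.to_csv(out / "topology_vs_age.tsv", sep="\t")
            soil_cols = [c for c in SOIL_VARIABLES if c in samples.frame.columns]
            if soil_cols:
                extra = [c for c in ("clustering_coefficient", "diameter")
                         if c in sub_topo.columns]
                rho, pv, stars = topology_vs_soil(
                    sub_topo[present + extra],
                    samples.soil().reindex(sub_topo.index),
                )
                rho.to_csv(out / "topology_vs_soil_rho.tsv", sep="\t")
                pv.to_csv(out / "topology_vs_soil_p.tsv", sep="\t")
                stars.to_csv(out / "topology_vs_soil_stars.tsv", sep="\t")
            report["topology_vs_age"] = {
                k: {"r": float(v["r"]), "p": float(v["p"])}
                for k, v in vs_age.iterrows()
            }

    with _stage("manifest", out):
        artifacts = {
            f.name: _checksum(f)
            for f in sorted(out.iterdir())
            if f.is_file() and f.name not in ("manifest.json", "FAILED")
        }
        report["artifacts"] = artifacts
        cio.write_json(report, out / "manifest.json")
    return report
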