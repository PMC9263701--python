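"""Synthetic chronosequence community generator.

Emulates the statistical structure the downstream analysis assumes: a
three-site tea-plantation chronosequence (plus adjacent forests) sampled in
triplicate plots, family-level 16S count tables with log-normal-like
abundance marginals and age-group-dependent correlation blocks (associations
tighten with stand age), sequencing depths in the observed per-sample range,
and soil chemistry in which total organic carbon (TOC) and microbial biomass
nitrogen (MBN) increase with stand age while the remaining properties
fluctuate around field-realistic magnitudes.

Counts are generated through a latent Gaussian copula: per sample a latent
normal vector with the age group's block-correlation matrix is pushed
through per-family log-normal marginals to expected relative abundances,
normalized, and realized as a multinomial draw at the sample's depth. The
copula guarantees a valid joint distribution for arbitrary block structure
while keeping heavy-tailed marginals typical of relative abundance data.

The generator also emits a *truth record* — the planted within-block family
pairs per age group and the planted soil slopes — so network-recovery and
trend-recovery can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import AGE_GROUPS, AgeGroupBins, OtuTable, SampleTable, TaxonomyTable, ValidationError

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate_dataset", "truth_edge_set"]

#: Default study design: site -> list of stands ("F" = adjacent forest,
#: integers = stand age in years). Forests exist only at HZ and JL.
DEFAULT_DESIGN: dict[str, tuple[object, ...]] = {
    "TRI": (10, 90),
    "HZ": (13, 50, 90, "F"),
    "JL": (3, 21, 43, "F"),
}

#: Dominant phyla first; weights below make Proteobacteria/Actinobacteria/
#: Acidobacteria carry most of the community, as in acidic tea-garden soils.
DEFAULT_PHYLA = (
    "Proteobacteria", "Actinobacteria", "Acidobacteria", "Chloroflexi",
    "Firmicutes", "Bacteroidetes", "Planctomycetes", "Verrucomicrobia",
    "Gemmatimonadetes", "Nitrospirae", "Chlamydiae", "Armatimonadetes",
)

DEFAULT_PHYLUM_WEIGHTS = (
    0.30, 0.18, 0.14, 0.09, 0.07, 0.06, 0.04, 0.035, 0.03, 0.02, 0.02, 0.015,
)

#: Correlation tightening with stand age: within-block latent correlation
#: rises from forest to the oldest stands.
DEFAULT_RHO_SCHEDULE: dict[str, float] = {
    "F": 0.60, "Y3_20": 0.75, "Y40_50": 0.85, "Y90": 0.92,
}

#: Age-independent soil properties: (mean, sd) around field magnitudes.
DEFAULT_SOIL_NOISE: dict[str, tuple[float, float]] = {
    "TON": (0.14, 0.03),
    "CN": (11.0, 1.0),
    "MBC": (350.0, 120.0),
    "AP": (30.0, 15.0),
    "ExchK": (75.0, 15.0),
    "ExchCa": (500.0, 200.0),
    "ExchMg": (35.0, 10.0),
    "ExchNa": (5.0, 1.5),
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic chronosequence.

    ``blocks`` maps each age group to a list of ``(block_size, rho)`` pairs;
    block members are taken from the front of the family list, consecutively,
    so the same families form blocks in every group while the within-block
    correlation follows the group's rho. Soil trends are linear in stand age
    with Gaussian noise: ``TOC = toc_intercept + toc_slope * age + eps`` and
    likewise for MBN; pH is age-independent Normal(ph_mean, ph_sd).
    """

    seed: int = 0
    design: Mapping[str, Sequence[object]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_DESIGN.items()}
    )
    plots_per_stand: int = 3
    n_families: int = 60
    phyla: Sequence[str] = DEFAULT_PHYLA
    phylum_weights: Sequence[float] = DEFAULT_PHYLUM_WEIGHTS
    depth_range: tuple[int, int] = (7265, 9204)
    blocks: Mapping[str, Sequence[tuple[int, float]]] | None = None
    rho_schedule: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RHO_SCHEDULE))
    block_sizes: Sequence[int] = (5, 5, 5)
    lognormal_sigma: float = 1.0
    toc_intercept: float = 1.05
    toc_slope: float = 0.018
    toc_sd: float = 0.10
    mbn_intercept: float = 10.0
    mbn_slope: float = 0.35
    mbn_sd: float = 2.5
    ph_mean: float = 4.1
    ph_sd: float = 0.2
    soil_noise: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SOIL_NOISE)
    )
    bins: AgeGroupBins = field(default_factory=AgeGroupBins)

    def resolved_blocks(self) -> dict[str, list[tuple[int, float]]]:
        """Blocks per age group; default = ``block_sizes`` at the group's rho."""
        if self.blocks is not None:
            out = {g: [(int(s), float(r)) for s, r in self.blocks[g]] for g in self.blocks}
        else:
            out = {
                g: [(int(s), float(self.rho_schedule[g])) for s in self.block_sizes]
                for g in AGE_GROUPS
            }
        for g, blocks in out.items():
            total = sum(s for s, _ in blocks)
            if total > self.n_families:
                raise ValidationError(
                    f"group {g}: block sizes sum to {total} > n_families {self.n_families}"
                )
            for s, r in blocks:
                if not (-1.0 < r < 1.0):
                    raise ValidationError(f"group {g}: rho {r} outside (-1, 1)")
        return out

    def validate(self) -> None:
        lo, hi = self.depth_range
        if not (0 < lo <= hi):
            raise ValidationError(f"invalid depth range {self.depth_range}")
        if len(self.phylum_weights) != len(self.phyla):
            raise ValidationError("phylum_weights length must match phyla")
        if self.plots_per_stand < 1:
            raise ValidationError("plots_per_stand must be >= 1")
        self.resolved_blocks()

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        raw = yaml.safe_load(open(path)) or {}
        if "design" in raw:
            raw["design"] = {k: tuple(v) for k, v in raw["design"].items()}
        if "blocks" in raw and raw["blocks"] is not None:
            raw["blocks"] = {g: [tuple(b) for b in bs] for g, bs in raw["blocks"].items()}
        if "bins" in raw and isinstance(raw["bins"], dict):
            raw["bins"] = AgeGroupBins(**raw["bins"])
        if "depth_range" in raw:
            raw["depth_range"] = tuple(raw["depth_range"])
        return cls(**raw)


@dataclass
class SimulatedDataset:
    table: OtuTable
    taxonomy: TaxonomyTable
    samples: SampleTable
    truth: dict


def _family_names(config: SimulationConfig) -> tuple[list[str], pd.DataFrame]:
    """Deterministic family list and lineage frame honoring phylum weights."""
    n_phyla = len(config.phyla)
    weights = np.asarray(config.phylum_weights, dtype=float)
    weights = weights / weights.sum()
    # proportional allocation of families to phyla, at least one each
    alloc = np.maximum(1, np.round(weights * config.n_families).astype(int))
    while alloc.sum() > config.n_families:
        alloc[np.argmax(alloc)] -= 1
    while alloc.sum() < config.n_families:
        alloc[np.argmin(alloc / weights)] += 1
    names, rows = [], []
    for p_idx, (phylum, k) in enumerate(zip(config.phyla, alloc)):
        for j in range(k):
            fam = f"{phylum[:4]}_fam{j + 1:02d}"
            names.append(fam)
            rows.append(
                {
                    "kingdom": "Bacteria",
                    "phylum": phylum,
                    "class": f"{phylum}_class",
                    "order": f"{phylum}_order",
                    "family": fam,
                    "genus": "unclassified",
                }
            )
    frame = pd.DataFrame(rows, index=names)
    return names, frame


def _block_members(config: SimulationConfig, group: str) -> list[list[int]]:
    blocks = config.resolved_blocks()[group]
    members, start = [], 0
    for size, _ in blocks:
        members.append(list(range(start, start + size)))
        start += size
    return members


def _correlation_matrix(config: SimulationConfig, group: str) -> np.ndarray:
    n = config.n_families
    sigma = np.eye(n)
    for (size, rho), idx in zip(config.resolved_blocks()[group], _block_members(config, group)):
        for a in idx:
            for b in idx:
                if a != b:
                    sigma[a, b] = rho
    return sigma


def _base_log_means(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-family log-scale abundance baselines; phylum weight enters as a shift."""
    _, lineages = _family_names(config)
    weights = dict(zip(config.phyla, np.asarray(config.phylum_weights, float)))
    counts = lineages["phylum"].value_counts()
    mu = np.empty(len(lineages))
    for i, (fam, row) in enumerate(lineages.iterrows()):
        per_family = weights[row["phylum"]] / counts[row["phylum"]]
        mu[i] = np.log(per_family) + rng.normal(0.0, 0.3)
    return mu


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate a complete synthetic dataset (counts, taxonomy, metadata, truth).

    Reproducible from ``config.seed`` alone: a root SeedSequence spawns named
    substreams (baselines, depths, soil, one per sample) so per-sample
    generation order cannot perturb other streams.
    """
    config = config or SimulationConfig()
    config.validate()

    design = [(site, stand) for site, stands in config.design.items() for stand in stands]
    sample_rows = []
    for site, stand in design:
        for plot in range(1, config.plots_per_stand + 1):
            if stand == "F":
                land_use, age = "forest", np.nan
                label = f"{site}_F_p{plot}"
            else:
                land_use, age = "tea", float(stand)
                label = f"{site}_Y{int(stand)}_p{plot}"
            sample_rows.append(
                {
                    "sample_id": label,
                    "site": site,
                    "stand_age": age,
                    "land_use": land_use,
                    "plot": f"p{plot}",
                    "age_group": config.bins.assign(
                        None if np.isnan(age) else age, land_use
                    ),
                }
            )
    meta = pd.DataFrame(sample_rows).set_index("sample_id")
    n_samples = len(meta)

    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(3 + n_samples)
    rng_base = np.random.default_rng(streams[0])
    rng_depth = np.random.default_rng(streams[1])
    rng_soil = np.random.default_rng(streams[2])
    sample_streams = streams[3:]

    family_ids, lineages = _family_names(config)
    mu = _base_log_means(config, rng_base)
    sigmas = {g: _correlation_matrix(config, g) for g in AGE_GROUPS}
    chols = {}
    for g, s in sigmas.items():
        try:
            chols[g] = np.linalg.cholesky(s)
        except np.linalg.LinAlgError as exc:
            raise ValidationError(
                f"block correlation matrix for group {g} is not positive definite"
            ) from exc

    lo, hi = config.depth_range
    depths = rng_depth.integers(lo, hi + 1, size=n_samples)

    counts = np.zeros((n_samples, config.n_families), dtype=np.int64)
    for i, (sample_id, row) in enumerate(meta.iterrows()):
        rng = np.random.default_rng(sample_streams[i])
        z = chols[row["age_group"]] @ rng.standard_normal(config.n_families)
        abundance = np.exp(mu + config.lognormal_sigma * z)
        proportions = abundance / abundance.sum()
        counts[i] = rng.multinomial(depths[i], proportions)

    table = OtuTable(pd.DataFrame(counts, index=meta.index, columns=family_ids))
    taxonomy = TaxonomyTable(lineages)

    ages = meta["stand_age"].fillna(0.0).to_numpy(float)
    soil = pd.DataFrame(index=meta.index)
    soil["pH"] = np.clip(rng_soil.normal(config.ph_mean, config.ph_sd, n_samples), 3.0, 6.5)
    soil["TOC"] = np.clip(
        config.toc_intercept + config.toc_slope * ages
        + rng_soil.normal(0.0, config.toc_sd, n_samples),
        0.05, None,
    )
    soil["MBN"] = np.clip(
        config.mbn_intercept + config.mbn_slope * ages
        + rng_soil.normal(0.0, config.mbn_sd, n_samples),
        0.1, None,
    )
    for var, (mean, sd) in config.soil_noise.items():
        soil[var] = np.clip(rng_soil.normal(mean, sd, n_samples), 0.01, None)
    samples = SampleTable(meta.join(soil))

    planted = {
        g: sorted(
            tuple(sorted((family_ids[a], family_ids[b])))
            for idx in _block_members(config, g)
            for k, a in enumerate(idx)
            for b in idx[k + 1:]
        )
        for g in AGE_GROUPS
    }
    truth = {
        "planted_edges": planted,
        "blocks": {
            g: [[family_ids[i] for i in idx] for idx in _block_members(config, g)]
            for g in AGE_GROUPS
        },
        "rho": {g: [r for _, r in config.resolved_blocks()[g]] for g in AGE_GROUPS},
        "soil_slopes": {"TOC": config.toc_slope, "MBN": config.mbn_slope},
        "seed": config.seed,
    }
    return SimulatedDataset(table=table, taxonomy=taxonomy, samples=samples, truth=truth)


def truth_edge_set(truth: dict, age_group: str) -> set[tuple[str, str]]:
    """Planted within-block family pairs for one age group, as sorted tuples."""
    planted = truth["planted_edges"]
    if age_group not in planted:
        raise KeyError(f"unknown age group {age_group!r}; have {sorted(planted)}")
    return {tuple(pair) for pair in planted[age_group]}
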