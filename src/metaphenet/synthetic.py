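"""Synthetic multi-omics study generator with known ground truth.

Emulates the data structure of a soil perturbation experiment: a master
metabolite-reaction network (a stand-in for a curated biochemical reaction
map), a log2-scale expression matrix of EC-numbered gene functions across
condition x site x replicate samples, and per-condition detected-metabolite
lists. Ground truth is planted so downstream stages can be scored:

* each non-control condition gets a pendant chain of ``pathway_length``
  reactions hung off a core metabolite, annotated with fresh EC numbers —
  these ECs are the condition's responsive genes and the chain metabolites
  its signature metabolite terminals;
* disjoint co-expression modules share a latent per-sample factor;
* a core metabolite pool is detected (near-)identically across conditions.

Every output is a pure function of the configuration: generators draw from
independent named streams derived from ``config.seed``, so regenerating one
artifact never perturbs another.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .config import ConfigurationError, SyntheticConfig
from .network import MetabolicNetwork, Reaction

__all__ = [
    "PlantedTruth",
    "generate_master_network",
    "generate_expression",
    "generate_metabolite_detections",
    "sample_conditions",
]


def _stream(seed: int, label: str) -> np.random.Generator:
    """Independent RNG stream keyed by (seed, label)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])
    )


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator.

    ``responsive_genes`` maps each non-control condition to the EC set of
    its planted reaction chain (disjoint across conditions by construction);
    ``terminal_metabolites`` maps it to the chain metabolites plus the core
    attachment point; ``module_membership`` maps genes to a planted
    co-expression module id (genes outside modules are absent).
    """

    module_membership: dict[str, int]
    responsive_genes: dict[str, frozenset[str]]
    terminal_metabolites: dict[str, frozenset[str]]
    core_metabolites: frozenset[str] = frozenset()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_membership": dict(sorted(self.module_membership.items())),
            "responsive_genes": {
                c: sorted(g) for c, g in sorted(self.responsive_genes.items())
            },
            "terminal_metabolites": {
                c: sorted(m) for c, m in sorted(self.terminal_metabolites.items())
            },
            "core_metabolites": sorted(self.core_metabolites),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            module_membership=payload["module_membership"],
            responsive_genes={
                c: frozenset(g) for c, g in payload["responsive_genes"].items()
            },
            terminal_metabolites={
                c: frozenset(m) for c, m in payload["terminal_metabolites"].items()
            },
            core_metabolites=frozenset(payload.get("core_metabolites", [])),
        )


@dataclass
class _World:
    network: MetabolicNetwork
    truth: PlantedTruth
    genes: list[str]


def _ec_string(rng: np.random.Generator, top: int) -> str:
    return (
        f"{top}.{rng.integers(1, 21)}.{rng.integers(1, 21)}.{rng.integers(1, 100)}"
    )


def _unique_ecs(rng: np.random.Generator, n: int, top: int) -> list[str]:
    ecs: list[str] = []
    seen: set[str] = set()
    while len(ecs) < n:
        ec = _ec_string(rng, top)
        if ec not in seen:
            seen.add(ec)
            ecs.append(ec)
    return ecs


def _side_count(rng: np.random.Generator, mean_degree: float, cap: int) -> int:
    n = 1 + int(rng.poisson(max(mean_degree - 1.0, 0.0)))
    return max(1, min(n, cap))


def _build_world(config: SyntheticConfig) -> _World:
    rng = _stream(config.seed, "master_network")
    perturbations = config.perturbations
    chain_len = config.pathway_length
    n_chain_rxns = chain_len * len(perturbations)
    n_chain_mets = n_chain_rxns

    plant = (
        config.n_reactions > n_chain_rxns and config.n_metabolites > n_chain_mets + 1
    )
    n_bg_r = config.n_reactions - (n_chain_rxns if plant else 0)
    n_bg_m = config.n_metabolites - (n_chain_mets if plant else 0)
    if n_bg_m < 2:
        raise ConfigurationError(
            "network shape infeasible: need >=2 background metabolites to place "
            "a substrate and a product"
        )

    width_m = max(4, len(str(config.n_metabolites)))
    width_r = max(4, len(str(config.n_reactions)))
    met_names = [f"M{i:0{width_m}d}" for i in range(config.n_metabolites)]
    rxn_names = [f"R{i:0{width_r}d}" for i in range(config.n_reactions)]
    bg_mets = met_names[:n_bg_m]
    chain_mets_pool = met_names[n_bg_m:]
    bg_rxns = rxn_names[:n_bg_r]
    chain_rxns_pool = rxn_names[n_bg_r:]

    # EC pool for background reactions; ~20% of reactions reuse a pool EC so
    # one function can annotate several reactions, as in curated maps.
    pool = _unique_ecs(rng, max(1, int(round(0.8 * n_bg_r))), top=int(rng.integers(1, 7)))

    reactions: dict[str, Reaction] = {}
    used: list[str] = []
    unused = list(bg_mets)
    for j, rid in enumerate(bg_rxns):
        n_sub = _side_count(rng, config.mean_reaction_degree, n_bg_m - 1)
        n_prod = _side_count(rng, config.mean_reaction_degree, n_bg_m - n_sub)
        chosen: list[str] = []
        if j > 0:
            # anchor to the already-connected part so the graph stays in one piece
            chosen.append(used[int(rng.integers(len(used)))])
        while len(chosen) < n_sub + n_prod:
            if unused:
                pick = unused[int(rng.integers(len(unused)))]
            else:
                pick = bg_mets[int(rng.integers(n_bg_m))]
            if pick not in chosen:
                chosen.append(pick)
                if pick in unused:
                    unused.remove(pick)
        for m in chosen:
            if m not in used:
                used.append(m)
        n_ec = 2 if rng.random() < 0.2 else 1
        ecs = tuple(
            dict.fromkeys(pool[int(rng.integers(len(pool)))] for _ in range(n_ec))
        )
        reactions[rid] = Reaction(rid, tuple(chosen[:n_sub]), tuple(chosen[n_sub:]), ecs)

    in_graph = sorted(used)
    n_core = min(config.n_core_metabolites, len(in_graph))
    core = sorted(rng.choice(in_graph, size=n_core, replace=False).tolist())

    responsive: dict[str, frozenset[str]] = {}
    terminals: dict[str, frozenset[str]] = {}
    if plant:
        chain_ecs = _unique_ecs(rng, n_chain_rxns, top=7)
        for k, cond in enumerate(perturbations):
            attach = core[int(rng.integers(len(core)))]
            mets = chain_mets_pool[k * chain_len : (k + 1) * chain_len]
            rids = chain_rxns_pool[k * chain_len : (k + 1) * chain_len]
            ecs = chain_ecs[k * chain_len : (k + 1) * chain_len]
            prev = attach
            for rid, met, ec in zip(rids, mets, ecs):
                reactions[rid] = Reaction(rid, (prev,), (met,), (ec,))
                prev = met
            responsive[cond] = frozenset(ecs)
            terminals[cond] = frozenset(mets) | {attach}

    network = MetabolicNetwork(reactions=reactions)
    graph = network.to_graph()
    if graph.number_of_nodes():
        frac = max(len(c) for c in nx.connected_components(graph)) / graph.number_of_nodes()
        if frac < 0.9:
            raise ConfigurationError(
                f"network shape infeasible: largest component holds only "
                f"{frac:.0%} of nodes; increase n_reactions or mean_reaction_degree"
            )

    network_ecs = sorted(network.ec_numbers)
    if len(network_ecs) > config.n_genes:
        raise ConfigurationError(
            f"n_genes={config.n_genes} smaller than the {len(network_ecs)} EC "
            "functions in the master network"
        )
    rng_fill = _stream(config.seed, "filler_genes")
    fillers = _unique_ecs(rng_fill, config.n_genes - len(network_ecs), top=9)
    genes = network_ecs + fillers

    rng_mod = _stream(config.seed, "modules")
    responsive_all = set().union(*responsive.values()) if responsive else set()
    candidates = [g for g in genes if g not in responsive_all]
    need = config.n_modules * config.module_size
    if need > len(candidates):
        raise ConfigurationError(
            f"cannot plant {config.n_modules} disjoint modules of size "
            f"{config.module_size}: only {len(candidates)} eligible genes"
        )
    module_genes = rng_mod.choice(candidates, size=need, replace=False)
    membership = {
        str(g): i // config.module_size for i, g in enumerate(module_genes)
    }

    truth = PlantedTruth(
        module_membership=membership,
        responsive_genes=responsive,
        terminal_metabolites=terminals,
        core_metabolites=frozenset(core),
    )
    return _World(network=network, truth=truth, genes=genes)


def generate_master_network(config: SyntheticConfig) -> MetabolicNetwork:
    """Generate the master metabolite-reaction network for this configuration."""
    return _build_world(config).network


def site_names(n_sites: int) -> list[str]:
    if n_sites <= 26:
        return [chr(ord("A") + i) for i in range(n_sites)]
    return [f"S{i + 1}" for i in range(n_sites)]


def sample_names(config: SyntheticConfig) -> list[str]:
    return [
        f"{cond}_{site}_r{rep + 1}"
        for cond in config.conditions
        for site in site_names(config.n_sites)
        for rep in range(config.n_replicates)
    ]


def sample_conditions(columns) -> pd.Series:
    """Condition label of each ``<condition>_<site>_<rep>`` sample id."""
    labels = []
    for col in columns:
        parts = str(col).split("_")
        if len(parts) != 3:
            raise ValueError(
                f"sample id {col!r} not of the form <condition>_<site>_<rep>"
            )
        labels.append(parts[0])
    return pd.Series(labels, index=list(columns), name="condition")


def sample_sites(columns) -> pd.Series:
    """Site label of each ``<condition>_<site>_<rep>`` sample id."""
    return pd.Series(
        [str(c).split("_")[1] for c in columns], index=list(columns), name="site"
    )


def generate_expression(
    config: SyntheticConfig, network: MetabolicNetwork
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Simulate the log2 expression matrix and return it with the planted truth.

    Genes are the network's EC functions plus filler functions up to
    ``n_genes``. A gene's value is baseline + module factor + condition
    shift + replicate noise, clipped at zero; planted responsive genes are
    shifted by log2(responsive_fold_change) in their own condition only.
    """
    world = _build_world(config)
    if not world.network.to_frame().equals(network.to_frame()):
        raise ValueError("network was not generated from this configuration")
    truth, genes = world.truth, world.genes

    samples = sample_names(config)
    conds = sample_conditions(samples).to_numpy()
    n_g, n_s = len(genes), len(samples)

    baseline = _stream(config.seed, "baseline").normal(6.0, 1.0, size=n_g)
    values = np.tile(baseline[:, None], (1, n_s))

    if config.latent_strength > 0 and truth.module_membership:
        rng_lat = _stream(config.seed, "latent")
        factors = rng_lat.normal(0.0, 1.0, size=(config.n_modules, n_s))
        gene_index = {g: i for i, g in enumerate(genes)}
        for gene, module in truth.module_membership.items():
            values[gene_index[gene]] += config.latent_strength * factors[module]

    shift = np.log2(config.responsive_fold_change)
    if shift > 0:
        gene_index = {g: i for i, g in enumerate(genes)}
        for cond, ecs in truth.responsive_genes.items():
            mask = conds == cond
            for ec in ecs:
                values[gene_index[ec], mask] += shift

    if config.noise_sd > 0:
        values = values + _stream(config.seed, "noise").normal(
            0.0, config.noise_sd, size=(n_g, n_s)
        )

    expr = pd.DataFrame(np.maximum(values, 0.0), index=genes, columns=samples)
    expr.index.name = "gene"
    return expr, truth


def generate_metabolite_detections(
    network: MetabolicNetwork, truth: PlantedTruth, config: SyntheticConfig
) -> dict[str, list[str]]:
    """Per-condition detected-metabolite lists.

    The core pool is subsampled once at ``metabolite_detection_rate`` and
    shared by every condition (detected metabolites are near-identical
    across perturbations); each condition additionally always detects its
    planted terminal metabolites. All listed metabolites exist in the
    network.
    """
    rng = _stream(config.seed, "detections")
    core = sorted(truth.core_metabolites)
    sampled = {m for m in core if rng.random() < config.metabolite_detection_rate}
    # chain attachment points are common core compounds: always detected, in
    # every condition, so their connection into the core is never
    # condition-specific
    attachments = set()
    for mets in truth.terminal_metabolites.values():
        attachments |= set(mets) & truth.core_metabolites
    detected_core = sorted(sampled | attachments)
    out: dict[str, list[str]] = {}
    for cond in config.conditions:
        planted = truth.terminal_metabolites.get(cond, frozenset())
        out[cond] = sorted(set(detected_core) | set(planted))
    return out


def detections_to_frame(detections: dict[str, list[str]]) -> pd.DataFrame:
    rows = [
        {"condition": cond, "metabolite_id": met}
        for cond in sorted(detections)
        for met in detections[cond]
    ]
    return pd.DataFrame(rows, columns=["condition", "metabolite_id"])


def detections_from_frame(frame: pd.DataFrame) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for cond, group in frame.groupby("condition"):
        out[str(cond)] = sorted(group["metabolite_id"].astype(str))
    return out
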