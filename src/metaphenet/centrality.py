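"""Centrality analysis of the co-expression network's main component.

Betweenness is Brandes shortest-path betweenness on the undirected
unweighted graph, normalized by 2/((n-1)(n-2)) with endpoint pairs
excluded; degree is the incident edge count. Condition-specific gene sets
are overlaid to summarize group centralities against the network-wide
means, and seed-gene neighborhoods are extracted for inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "compute_centralities",
    "rank_genes",
    "group_summary",
    "ratio_to_median",
    "neighborhood_subnetwork",
    "NeighborhoodSubnetwork",
]

log = logging.getLogger(__name__)


def compute_centralities(net: nx.Graph) -> pd.DataFrame:
    """Normalized betweenness and degree per node, indexed by gene id.

    Intended for a connected network (run on the largest component); for
    fewer than three nodes betweenness is defined as zero.
    """
    nodes = sorted(net.nodes)
    if len(nodes) < 3:
        betweenness = {n: 0.0 for n in nodes}
    else:
        betweenness = nx.betweenness_centrality(net, normalized=True)
    table = pd.DataFrame(
        {
            "betweenness": [betweenness[n] for n in nodes],
            "degree": [net.degree(n) for n in nodes],
        },
        index=pd.Index(nodes, name="gene"),
    )
    return table


def rank_genes(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Table sorted by ``metric`` descending with a 1-based ``rank`` column.

    Ties are broken by lexicographic gene id (smaller id ranks first).
    """
    if metric not in table.columns:
        raise ValueError(f"unknown metric {metric!r}")
    if table.empty:
        raise ValueError("empty centrality table")
    ordered = table.assign(_gene=table.index).sort_values(
        by=[metric, "_gene"], ascending=[False, True]
    )
    ordered = ordered.drop(columns="_gene")
    ordered["rank"] = np.arange(1, len(ordered) + 1)
    return ordered


def group_summary(
    table: pd.DataFrame,
    labels: dict[str, set[str] | frozenset[str]],
    network_mean_betweenness: float | None = None,
    network_mean_degree: float | None = None,
) -> pd.DataFrame:
    """Per-group centrality aggregates against the network-wide means.

    ``labels`` maps a condition name to its gene set; genes absent from the
    table are reported (logged) and excluded from the means. The
    network-wide means default to the table's own means but can be supplied
    externally (e.g. when the table is a labeled subset of a larger
    network). "Below average" counts use strict ``<``.
    """
    net_mean_b = (
        float(table["betweenness"].mean())
        if network_mean_betweenness is None
        else float(network_mean_betweenness)
    )
    net_mean_d = (
        float(table["degree"].mean())
        if network_mean_degree is None
        else float(network_mean_degree)
    )
    rows = []
    for group in sorted(labels):
        genes = sorted(set(labels[group]))
        present = [g for g in genes if g in table.index]
        missing = sorted(set(genes) - set(present))
        if missing:
            log.warning("group %s: %d gene(s) not in table: %s", group, len(missing), missing)
        sub = table.loc[present]
        n = len(present)
        row = {
            "group": group,
            "n_genes": n,
            "n_missing": len(missing),
            "mean_betweenness": float(sub["betweenness"].mean()) if n else float("nan"),
            "mean_degree": float(sub["degree"].mean()) if n else float("nan"),
        }
        row["fold_betweenness"] = (
            row["mean_betweenness"] / net_mean_b if n and net_mean_b > 0 else float("nan")
        )
        row["fold_degree"] = (
            row["mean_degree"] / net_mean_d if n and net_mean_d > 0 else float("nan")
        )
        row["n_below_mean_betweenness"] = int((sub["betweenness"] < net_mean_b).sum())
        row["n_below_mean_degree"] = int((sub["degree"] < net_mean_d).sum())
        rows.append(row)
    out = pd.DataFrame(rows).set_index("group")
    out.attrs["network_mean_betweenness"] = net_mean_b
    out.attrs["network_mean_degree"] = net_mean_d
    return out


def ratio_to_median(table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene centrality ratios to the network medians.

    Returns ``log2_betweenness_ratio`` (log2 of betweenness over median
    betweenness) and ``degree_ratio`` (degree over median degree, linear).
    Zero-betweenness genes cannot be log-transformed and are floored at
    one tenth of the smallest positive betweenness (flagged in
    ``betweenness_floored``); a zero median gets the same floor.
    """
    betweenness = table["betweenness"].to_numpy(float)
    degree = table["degree"].to_numpy(float)
    positive = betweenness[betweenness > 0]
    floor = positive.min() / 10.0 if positive.size else 1.0
    med_b = float(np.median(betweenness))
    if med_b <= 0:
        log.warning("zero median betweenness; substituting floor %g", floor)
        med_b = floor
    med_d = float(np.median(degree))
    floored = betweenness <= 0
    safe_b = np.where(floored, floor, betweenness)
    return pd.DataFrame(
        {
            "log2_betweenness_ratio": np.log2(safe_b / med_b),
            "degree_ratio": degree / med_d,
            "betweenness_floored": floored,
        },
        index=table.index,
    )


@dataclass
class NeighborhoodSubnetwork:
    """Seed genes, their first neighbors, and the induced edge set."""

    seeds: frozenset[str]
    members: frozenset[str]
    edges: frozenset[tuple[str, str]]
    dropped_seeds: frozenset[str] = frozenset()
    missing_seeds: frozenset[str] = frozenset()


def neighborhood_subnetwork(
    net: nx.Graph, seeds, drop_isolated_seeds: bool = False
) -> NeighborhoodSubnetwork:
    """First-neighborhood subnetwork around a seed gene set.

    Members are the seeds plus every node adjacent to at least one seed;
    the edge set is induced from the parent network. With
    ``drop_isolated_seeds``, a seed whose neighborhood shares no member
    with the rest of the seed cluster is excluded (the rule used to drop a
    seed gene not in proximity to the others).
    """
    seed_list = sorted(set(seeds))
    missing = frozenset(s for s in seed_list if s not in net)
    kept = [s for s in seed_list if s in net]
    if not kept:
        log.warning("no seeds present in the network")
        return NeighborhoodSubnetwork(
            seeds=frozenset(),
            members=frozenset(),
            edges=frozenset(),
            missing_seeds=missing,
        )

    closed = {s: {s} | set(net.neighbors(s)) for s in kept}
    dropped: set[str] = set()
    if drop_isolated_seeds and len(kept) > 1:
        for s in kept:
            cluster: set[str] = set()
            for t in kept:
                if t != s:
                    cluster |= closed[t]
            if not (set(net.neighbors(s)) | {s}) & cluster:
                dropped.add(s)
    final_seeds = [s for s in kept if s not in dropped]
    members: set[str] = set()
    for s in final_seeds:
        members |= closed[s]
    edges = frozenset(
        (u, v) if u <= v else (v, u)
        for u, v in net.subgraph(members).edges()
    )
    return NeighborhoodSubnetwork(
        seeds=frozenset(final_seeds),
        members=frozenset(members),
        edges=edges,
        dropped_seeds=frozenset(dropped),
        missing_seeds=missing,
    )
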