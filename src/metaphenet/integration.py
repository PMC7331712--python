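"""Minimal-subnetwork integration of metabolites and over-expressed genes.

For each condition (and site), the detected metabolites and the reactions
carrying over-expressed EC functions are treated as *terminals* on the
master metabolite-reaction graph, and a minimal connecting subnetwork is
extracted. "Minimal" is formalized as a minimum-edge-count Steiner tree on
the unweighted bipartite graph; the production algorithm is the classic
metric-closure / MST 2-approximation (shortest paths between terminals ->
MST of the terminal distance graph -> path expansion -> spanning tree ->
pruning of non-terminal leaves). An exhaustive exact solver is provided for
small instances as an independent check.

Terminals split across master-network components yield a Steiner *forest*
(one tree per terminal-bearing component) plus a warning, never a failure.
All tie-breaking is lexicographic on node/edge identifiers, so results are
bit-reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .network import MetabolicNetwork

__all__ = [
    "TerminalSet",
    "SubnetworkResult",
    "ConditionGeneTable",
    "build_terminals",
    "minimal_subnetwork",
    "steiner_tree_approx",
    "exact_steiner_oracle",
    "condition_gene_sets",
    "unique_genes",
    "pathway_annotation",
]

Edge = tuple[str, str]


def _edge(u, v) -> Edge:
    return (u, v) if u <= v else (v, u)


@dataclass
class TerminalSet:
    """Nodes that a condition's subnetwork must connect."""

    metabolite_terminals: frozenset[str]
    reaction_terminals: frozenset[str]
    provenance: dict[str, str]
    unmatched_metabolites: frozenset[str] = frozenset()
    unmatched_genes: frozenset[str] = frozenset()

    @property
    def nodes(self) -> frozenset[str]:
        return self.metabolite_terminals | self.reaction_terminals

    @property
    def empty(self) -> bool:
        return not self.nodes


@dataclass
class SubnetworkResult:
    """A minimal connecting subnetwork and the gene set it implicates."""

    nodes: frozenset[str]
    edges: frozenset[Edge]
    genes: frozenset[str]
    condition: str = ""
    site: str = ""
    is_forest: bool = False
    warnings: tuple[str, ...] = ()

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_terminals(
    network: MetabolicNetwork,
    metabolites,
    overexpressed,
) -> TerminalSet:
    """Map detected metabolites and over-expressed ECs onto network terminals.

    Metabolite terminals are the detected metabolites present in the
    network; gene terminals are every reaction whose EC annotation
    intersects the over-expressed set. Detected metabolites (or ECs) absent
    from the network are reported in ``unmatched_*``, never silently
    dropped.
    """
    known_mets = network.metabolites
    detected = set(metabolites)
    met_terms = frozenset(detected & known_mets)
    unmatched_mets = frozenset(detected - known_mets)

    known_ecs = network.ec_numbers
    over = set(overexpressed)
    rxn_terms: set[str] = set()
    for ec in over & known_ecs:
        rxn_terms.update(network.reactions_for_ec(ec))
    provenance: dict[str, str] = {m: "metabolite-detected" for m in met_terms}
    provenance.update({r: "gene-derived" for r in rxn_terms})
    return TerminalSet(
        metabolite_terminals=met_terms,
        reaction_terminals=frozenset(rxn_terms),
        provenance=provenance,
        unmatched_metabolites=unmatched_mets,
        unmatched_genes=frozenset(over - known_ecs),
    )


def _bfs_parents(graph: nx.Graph, source: str) -> dict[str, str | None]:
    """BFS parents with lexicographic neighbor order (deterministic paths)."""
    parents: dict[str, str | None] = {source: None}
    frontier = [source]
    while frontier:
        nxt: list[str] = []
        for node in frontier:
            for nbr in sorted(graph.neighbors(node)):
                if nbr not in parents:
                    parents[nbr] = node
                    nxt.append(nbr)
        frontier = nxt
    return parents


def _path_from_parents(parents: dict[str, str | None], target: str) -> list[str]:
    path = [target]
    while parents[path[-1]] is not None:
        path.append(parents[path[-1]])
    return path[::-1]


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _lex_spanning_tree(nodes, edges) -> set[Edge]:
    """Kruskal over lexicographically sorted unweighted edges.

    The greedy matroid argument makes this the lexicographically smallest
    spanning-tree edge set of a connected graph.
    """
    uf = _UnionFind(nodes)
    tree: set[Edge] = set()
    for u, v in sorted(edges):
        if uf.union(u, v):
            tree.add((u, v))
    return tree


def steiner_tree_approx(graph: nx.Graph, terminals) -> tuple[set[str], set[Edge]]:
    """Metric-closure 2-approximate Steiner tree on one component.

    All terminals must lie in a single connected component of ``graph``.
    Returns the tree's node and edge sets; a single terminal yields that
    node and no edges.
    """
    terms = sorted(set(terminals))
    if not terms:
        raise ValueError("need at least one terminal")
    for t in terms:
        if t not in graph:
            raise ValueError(f"terminal {t!r} not in graph")
    if len(terms) == 1:
        return {terms[0]}, set()

    parents = {t: _bfs_parents(graph, t) for t in terms}
    for t in terms[1:]:
        if t not in parents[terms[0]]:
            raise ValueError("terminals span multiple components")

    # metric closure restricted to terminals, then its MST (Kruskal,
    # ties broken on the terminal pair)
    closure_edges = []
    for a, b in itertools.combinations(terms, 2):
        dist = len(_path_from_parents(parents[a], b)) - 1
        closure_edges.append((dist, a, b))
    closure_edges.sort()
    uf = _UnionFind(terms)
    nodes: set[str] = set(terms)
    edges: set[Edge] = set()
    for _, a, b in closure_edges:
        if uf.union(a, b):
            path = _path_from_parents(parents[a], b)
            nodes.update(path)
            edges.update(_edge(u, v) for u, v in zip(path, path[1:]))

    # re-span the expanded subgraph and prune non-terminal leaves
    tree = _lex_spanning_tree(nodes, edges)
    term_set = set(terms)
    degree: dict[str, int] = {n: 0 for n in nodes}
    for u, v in tree:
        degree[u] += 1
        degree[v] += 1
    changed = True
    while changed:
        changed = False
        for u, v in sorted(tree):
            for leaf, other in ((u, v), (v, u)):
                if degree[leaf] == 1 and leaf not in term_set:
                    tree.discard((u, v))
                    degree[leaf] -= 1
                    degree[other] -= 1
                    changed = True
                    break
    kept = {n for e in tree for n in e} | term_set
    return kept, tree


def exact_steiner_oracle(graph: nx.Graph, terminals) -> tuple[set[str], set[Edge]]:
    """Exhaustive minimum-edge Steiner tree for small instances.

    Enumerates non-terminal node subsets in increasing size; the first size
    at which some subset union the terminals induces a connected subgraph
    gives the optimum (a tree on k nodes has k-1 edges, so fewest nodes =
    fewest edges). Ties are broken by the lexicographically smallest sorted
    edge list. Guarded to graphs of at most 15 nodes.
    """
    terms = sorted(set(terminals))
    if not terms:
        raise ValueError("need at least one terminal")
    if graph.number_of_nodes() > 15:
        raise ValueError("exact oracle limited to graphs with <= 15 nodes")
    for t in terms:
        if t not in graph:
            raise ValueError(f"terminal {t!r} not in graph")
    if len(terms) == 1:
        return {terms[0]}, set()

    others = sorted(set(graph.nodes) - set(terms))
    for size in range(len(others) + 1):
        candidates: list[tuple[list[Edge], set[str]]] = []
        for extra in itertools.combinations(others, size):
            node_set = set(terms) | set(extra)
            sub = graph.subgraph(node_set)
            if nx.is_connected(sub):
                tree = _lex_spanning_tree(node_set, sub.edges())
                candidates.append((sorted(tree), node_set))
        if candidates:
            best_edges, best_nodes = min(candidates)
            return best_nodes, set(best_edges)
    raise ValueError("terminals span multiple components")


def minimal_subnetwork(
    network: MetabolicNetwork,
    terminals: TerminalSet,
    condition: str = "",
    site: str = "",
) -> SubnetworkResult:
    """Minimal connecting subnetwork for one condition/site.

    Terminals in different master components each get their own tree
    (a Steiner forest, with a warning). An empty terminal set yields an
    empty, flagged result.
    """
    warnings = []
    if terminals.unmatched_metabolites:
        warnings.append(
            "metabolites not in network: "
            + ", ".join(sorted(terminals.unmatched_metabolites))
        )
    if terminals.unmatched_genes:
        warnings.append(
            "over-expressed ECs not in network: "
            + ", ".join(sorted(terminals.unmatched_genes))
        )
    if terminals.empty:
        warnings.append("nothing to connect: empty terminal set")
        return SubnetworkResult(
            nodes=frozenset(),
            edges=frozenset(),
            genes=frozenset(),
            condition=condition,
            site=site,
            warnings=tuple(warnings),
        )

    graph = network.to_graph()
    component_of: dict[str, int] = {}
    for i, comp in enumerate(
        sorted(nx.connected_components(graph), key=lambda c: (-len(c), min(c)))
    ):
        for node in comp:
            component_of[node] = i

    groups: dict[int, list[str]] = {}
    for t in sorted(terminals.nodes):
        groups.setdefault(component_of[t], []).append(t)

    all_nodes: set[str] = set()
    all_edges: set[Edge] = set()
    for comp_id in sorted(groups):
        nodes, edges = steiner_tree_approx(graph, groups[comp_id])
        all_nodes |= nodes
        all_edges |= edges
    is_forest = len(groups) > 1
    if is_forest:
        warnings.append(
            f"terminals split across {len(groups)} components; returning a forest"
        )
    reaction_nodes = [n for n in all_nodes if n in network.reactions]
    genes = frozenset(network.ecs_for_reactions(reaction_nodes))
    return SubnetworkResult(
        nodes=frozenset(all_nodes),
        edges=frozenset(all_edges),
        genes=genes,
        condition=condition,
        site=site,
        is_forest=is_forest,
        warnings=tuple(warnings),
    )


@dataclass
class ConditionGeneTable:
    """Per-condition implicated gene sets (union over sites) with unique flags."""

    gene_sets: dict[str, frozenset[str]]

    def unique_sets(self) -> dict[str, frozenset[str]]:
        out: dict[str, frozenset[str]] = {}
        for cond, genes in self.gene_sets.items():
            others: set[str] = set()
            for other_cond, other_genes in self.gene_sets.items():
                if other_cond != cond:
                    others |= other_genes
            out[cond] = frozenset(genes - others)
        return out

    def to_frame(self) -> pd.DataFrame:
        uniques = self.unique_sets()
        rows = [
            {"condition": cond, "gene": gene, "unique": gene in uniques[cond]}
            for cond in sorted(self.gene_sets)
            for gene in sorted(self.gene_sets[cond])
        ]
        return pd.DataFrame(rows, columns=["condition", "gene", "unique"])


def condition_gene_sets(results) -> ConditionGeneTable:
    """Union each condition's implicated genes over its sites."""
    sets: dict[str, set[str]] = {}
    for res in results:
        sets.setdefault(res.condition, set()).update(res.genes)
    if not sets:
        raise ValueError("no subnetwork results supplied")
    return ConditionGeneTable(
        gene_sets={c: frozenset(g) for c, g in sets.items()}
    )


def unique_genes(table: ConditionGeneTable) -> dict[str, frozenset[str]]:
    """Genes implicated in exactly one condition, per condition."""
    return table.unique_sets()


def pathway_annotation(genes, mapping: pd.DataFrame) -> dict[str, set[str]]:
    """Group genes by pathway via an EC -> pathway lookup table.

    ``mapping`` needs columns ``ec`` and ``pathway``; a gene may map to
    several pathways (it then appears in each group). Genes without any
    mapping are collected under ``"unmapped"``.
    """
    required = {"ec", "pathway"}
    if not required.issubset(mapping.columns):
        raise ValueError(f"mapping table needs columns {sorted(required)}")
    lookup: dict[str, set[str]] = {}
    for i, row in mapping.iterrows():
        ec, pathway = row["ec"], row["pathway"]
        if pd.isna(ec) or pd.isna(pathway) or not str(ec) or not str(pathway):
            raise ValueError(f"malformed mapping row at line {i + 2}")
        lookup.setdefault(str(ec), set()).add(str(pathway))
    groups: dict[str, set[str]] = {}
    for gene in sorted(set(genes)):
        pathways = lookup.get(gene)
        if not pathways:
            groups.setdefault("unmapped", set()).add(gene)
        else:
            for pw in pathways:
                groups.setdefault(pw, set()).add(gene)
    return groups
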