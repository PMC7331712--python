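"""Bipartite metabolite-reaction network container.

The master metabolic network is an undirected bipartite graph between
metabolite nodes and reaction nodes. Each reaction carries one or more
EC-number annotations; one EC number may annotate several reactions
(isoenzymes / promiscuous functions). Directionality is ignored: the
integration stage only needs undirected connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd


@dataclass(frozen=True)
class Reaction:
    reaction_id: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    ec_numbers: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise ValueError(
                f"reaction {self.reaction_id} needs >=1 substrate and >=1 product"
            )
        if set(self.substrates) & set(self.products):
            raise ValueError(
                f"reaction {self.reaction_id} lists a metabolite as both "
                "substrate and product"
            )
        if not self.ec_numbers:
            raise ValueError(f"reaction {self.reaction_id} has no EC annotation")


@dataclass
class MetabolicNetwork:
    """Master metabolic network as a reaction table plus derived views."""

    reactions: dict[str, Reaction]

    def __post_init__(self) -> None:
        self._graph: nx.Graph | None = None

    @property
    def reaction_ids(self) -> list[str]:
        return sorted(self.reactions)

    @property
    def metabolites(self) -> set[str]:
        mets: set[str] = set()
        for rxn in self.reactions.values():
            mets.update(rxn.substrates)
            mets.update(rxn.products)
        return mets

    @property
    def ec_numbers(self) -> set[str]:
        ecs: set[str] = set()
        for rxn in self.reactions.values():
            ecs.update(rxn.ec_numbers)
        return ecs

    def reactions_for_ec(self, ec: str) -> list[str]:
        """All reaction ids annotated with this EC number, sorted."""
        return sorted(
            rid for rid, rxn in self.reactions.items() if ec in rxn.ec_numbers
        )

    def ecs_for_reactions(self, reaction_ids) -> set[str]:
        ecs: set[str] = set()
        for rid in reaction_ids:
            ecs.update(self.reactions[rid].ec_numbers)
        return ecs

    def to_graph(self) -> nx.Graph:
        """Undirected bipartite graph; metabolite nodes have bipartite=0."""
        if self._graph is not None:
            return self._graph
        g = nx.Graph()
        for met in sorted(self.metabolites):
            g.add_node(met, bipartite=0, kind="metabolite")
        for rid in self.reaction_ids:
            rxn = self.reactions[rid]
            g.add_node(rid, bipartite=1, kind="reaction", ec=";".join(rxn.ec_numbers))
            for met in rxn.substrates:
                g.add_edge(rid, met, role="substrate")
            for met in rxn.products:
                g.add_edge(rid, met, role="product")
        self._graph = g
        return g

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "reaction_id": rid,
                "substrates": ";".join(rxn.substrates),
                "products": ";".join(rxn.products),
                "ec_numbers": ";".join(rxn.ec_numbers),
            }
            for rid, rxn in sorted(self.reactions.items())
        ]
        return pd.DataFrame(rows, columns=["reaction_id", "substrates", "products", "ec_numbers"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MetabolicNetwork":
        required = {"reaction_id", "substrates", "products", "ec_numbers"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"reaction table missing columns: {sorted(missing)}")
        reactions: dict[str, Reaction] = {}
        for i, row in frame.iterrows():
            rid = str(row["reaction_id"])
            if rid in reactions:
                raise ValueError(f"duplicate reaction id {rid!r} (row {i})")
            reactions[rid] = Reaction(
                reaction_id=rid,
                substrates=tuple(str(row["substrates"]).split(";")),
                products=tuple(str(row["products"]).split(";")),
                ec_numbers=tuple(str(row["ec_numbers"]).split(";")),
            )
        return cls(reactions=reactions)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MetabolicNetwork":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))
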