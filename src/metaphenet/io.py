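"""Readers and writers for the pipeline's plain-text formats.

TSV for matrices and tables, SIF and GraphML for networks, JSON for truth
and manifests. All writers iterate in sorted order so identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_expression(path: str | Path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col="gene")
    return expr


def write_sif(edges, path: str | Path, interaction: str = "co") -> None:
    """Simple interaction format: ``node<TAB>interaction<TAB>node`` per edge."""
    lines = [
        f"{u}\t{interaction}\t{v}"
        for u, v in sorted(tuple(sorted(e)) for e in edges)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_sif(path: str | Path) -> nx.Graph:
    net = nx.Graph()
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}: malformed SIF line {i}: {line!r}")
        net.add_edge(parts[0], parts[2])
    return net


def write_edge_tsv(edges, path: str | Path) -> None:
    frame = pd.DataFrame(
        sorted(tuple(sorted(e)) for e in edges), columns=["gene_a", "gene_b"]
    )
    frame.to_csv(path, sep="\t", index=False)


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    # rebuild with sorted insertion so the XML is deterministic
    ordered = nx.Graph()
    ordered.add_nodes_from(sorted(net.nodes))
    ordered.add_edges_from(sorted(tuple(sorted(e)) for e in net.edges))
    nx.write_graphml(ordered, path)


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
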