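"""Mixed regulatory network: typed nodes, directed/undirected typed edges
with provenance and confidence."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

NODE_TYPES = {"gene", "tf", "mirna"}
EDGE_PROVENANCES = {
    "coexpression", "curated", "motif", "bayesian", "mirna_target", "tf_mirna",
}


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    directed: bool
    provenance: tuple[str, ...]
    confidence: float = 1.0

    def key(self) -> tuple[str, str, bool]:
        if self.directed:
            return (self.source, self.target, True)
        a, b = sorted((self.source, self.target))
        return (a, b, False)


@dataclass
class RegulatoryNetwork:
    """Mixed graph; undirected edges are stored once with sorted endpoints."""

    node_types: dict[str, str] = field(default_factory=dict)
    edges: dict[tuple[str, str, bool], Edge] = field(default_factory=dict)

    def add_node(self, node: str, node_type: str = "gene") -> None:
        if node_type not in NODE_TYPES:
            raise ValueError(f"unknown node type {node_type!r}")
        self.node_types.setdefault(node, node_type)

    def add_edge(self, edge: Edge) -> None:
        for end in (edge.source, edge.target):
            self.add_node(end)
        key = edge.key()
        if key in self.edges:
            old = self.edges[key]
            prov = tuple(dict.fromkeys(old.provenance + edge.provenance))
            self.edges[key] = replace(old, provenance=prov,
                                      confidence=max(old.confidence, edge.confidence))
        else:
            self.edges[key] = edge

    @property
    def nodes(self) -> set[str]:
        return set(self.node_types)

    def directed_edges(self) -> list[Edge]:
        return [e for e in self.edges.values() if e.directed]

    def undirected_edges(self) -> list[Edge]:
        return [e for e in self.edges.values() if not e.directed]

    def remove_edges(self, keys: Iterable[tuple[str, str, bool]]) -> int:
        n = 0
        for key in list(keys):
            if key in self.edges:
                del self.edges[key]
                n += 1
        return n

    def copy(self) -> "RegulatoryNetwork":
        return RegulatoryNetwork(dict(self.node_types), dict(self.edges))

    # -- exports ------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": e.source,
                "target": e.target,
                "directed": e.directed,
                "provenance": "|".join(e.provenance),
                "confidence": e.confidence,
            }
            for e in sorted(self.edges.values(), key=lambda e: e.key())
        ]
        return pd.DataFrame(rows, columns=["source", "target", "directed",
                                           "provenance", "confidence"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   node_types: dict[str, str] | None = None) -> "RegulatoryNetwork":
        net = cls()
        for node, ntype in (node_types or {}).items():
            net.add_node(node, ntype)
        for row in df.itertuples(index=False):
            directed = bool(row.directed) if isinstance(row.directed, (bool,)) else \
                str(row.directed).lower() in {"true", "1"}
            net.add_edge(Edge(row.source, row.target, directed,
                              tuple(str(row.provenance).split("|")),
                              float(row.confidence)))
        return net

    @classmethod
    def read_tsv(cls, path: str | Path) -> "RegulatoryNetwork":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def to_networkx(self) -> nx.DiGraph:
        """Digraph view: undirected edges become arcs both ways."""
        g = nx.DiGraph()
        for node, ntype in self.node_types.items():
            g.add_node(node, node_type=ntype)
        for e in self.edges.values():
            attrs = {"provenance": "|".join(e.provenance),
                     "confidence": e.confidence, "directed": e.directed}
            g.add_edge(e.source, e.target, **attrs)
            if not e.directed:
                g.add_edge(e.target, e.source, **attrs)
        return g

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), path)
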