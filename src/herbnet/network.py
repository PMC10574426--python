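"""Heterogeneous compound-target-pathway-function network and degree ranking.

Relations produced by earlier stages (drug-compound, compound-target,
disease-target, pathway-target, function-target) are merged into one
undirected network whose nodes carry a type label. Core compounds and
core targets are the top-k nodes of each type by degree, where degree is
type-blind (it counts incident edges of every relation kind). Ties are
broken by ascending node id so rankings are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence, Tuple

import networkx as nx

NODE_TYPES = (
    "compound",
    "target",
    "pathway",
    "function_BP",
    "function_CC",
    "function_MF",
    "disease",
    "drug",
)


@dataclass
class RelationTable:
    """A typed bipartite edge table, e.g. compound-target pairs."""

    type_a: str
    type_b: str
    pairs: Sequence[Tuple[str, str]]

    def __post_init__(self) -> None:
        for t in (self.type_a, self.type_b):
            if t not in NODE_TYPES:
                raise ValueError(f"undeclared node type {t!r}; expected one of {NODE_TYPES}")


class RankEntry(NamedTuple):
    node: str
    node_type: str
    degree: int


def build_network(relations: Iterable[RelationTable]) -> nx.Graph:
    """Union of all relation tables as one typed undirected network.

    Duplicate edges collapse; a node id appearing with two different
    types is an error (ids are namespaced by the caller if needed).
    Self-loops are rejected.
    """
    g = nx.Graph()

    def add_node(node: str, node_type: str) -> None:
        prior = g.nodes.get(node, {}).get("node_type")
        if prior is not None and prior != node_type:
            raise ValueError(
                f"node {node!r} declared with conflicting types "
                f"{prior!r} and {node_type!r}"
            )
        g.add_node(node, node_type=node_type)

    for table in relations:
        for a, b in table.pairs:
            a, b = str(a), str(b)
            if a == b and table.type_a == table.type_b:
                raise ValueError(f"self-loop on node {a!r}")
            add_node(a, table.type_a)
            add_node(b, table.type_b)
            g.add_edge(a, b)
    return g


def rank_by_degree(net: nx.Graph, node_type: str, k: int) -> list[RankEntry]:
    """Top-k nodes of ``node_type`` by (type-blind) degree.

    Sorted descending by degree, then ascending by node id; when fewer
    than ``k`` nodes of the type exist, all are returned.
    """
    if node_type not in NODE_TYPES:
        raise ValueError(f"unknown node type {node_type!r}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    entries = [
        RankEntry(node=n, node_type=node_type, degree=net.degree(n))
        for n, data in net.nodes(data=True)
        if data.get("node_type") == node_type
    ]
    entries.sort(key=lambda e: (-e.degree, e.node))
    return entries[:k]


def to_sif(net: nx.Graph) -> str:
    """Cytoscape SIF export: one ``a<TAB>rel<TAB>b`` line per edge."""
    lines = []
    for a, b in sorted(net.edges, key=lambda e: tuple(sorted(map(str, e)))):
        a, b = sorted((str(a), str(b)))
        rel = "{}-{}".format(net.nodes[a]["node_type"], net.nodes[b]["node_type"])
        lines.append(f"{a}\t{rel}\t{b}")
    return "\n".join(lines) + ("\n" if lines else "")
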