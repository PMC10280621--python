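"""Minimum spanning tree of the complete distance graph G(S).

The MST weight is the quantity of interest — it upper-bounds the optimal
parsimony and is within a factor two of it — so the weight must be unique
and the returned tree deterministic. Several MSTs usually exist (the
four-DNA-sequence worked example already has three equally good first
edges); Kruskal is therefore run over edges pre-sorted by (weight,
lexicographic id pair), and the tree is rooted at the lexicographically
smallest id to give downstream algorithms a fixed orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
from networkx.utils import UnionFind


@dataclass(frozen=True)
class SpanningTree:
    """A rooted spanning tree with integer/real edge weights."""

    graph: nx.Graph
    root: str

    @property
    def vertices(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]

    @property
    def weight(self) -> float:
        return sum(w for _, _, w in self.edges)

    def parent_map(self) -> dict[str, str]:
        """Parent of every non-root vertex under the root orientation."""
        parents: dict[str, str] = {}
        for parent, child in nx.bfs_edges(self.graph, self.root):
            parents[child] = parent
        return parents


def minimum_spanning_tree(G: nx.Graph) -> SpanningTree:
    """Deterministic Kruskal MST of a connected weighted graph.

    Edges are examined in (weight, sorted id pair) order, so the result is
    reproducible even when multiple MSTs exist; the total weight is of course
    the same for all of them.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("cannot build a spanning tree of an empty graph")
    if not nx.is_connected(G):
        raise ValueError("graph is not connected")
    edges = sorted(
        ((d["weight"], *sorted((u, v))) for u, v, d in G.edges(data=True)),
    )
    T = nx.Graph()
    T.add_nodes_from(G.nodes)
    uf = UnionFind(G.nodes)
    for w, u, v in edges:
        if uf[u] != uf[v]:
            uf.union(u, v)
            T.add_edge(u, v, weight=w)
            if T.number_of_edges() == G.number_of_nodes() - 1:
                break
    return SpanningTree(T, root=min(G.nodes))


def tree_weight(tree) -> float:
    """Total weight of a SpanningTree, or parsimony weight of a Cladogram."""
    from .cladogram import Cladogram, parsimony_weight

    if isinstance(tree, Cladogram):
        return parsimony_weight(tree)
    return tree.weight
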