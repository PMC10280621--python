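"""Rooted labeled trees (cladograms) and the MST-to-cladogram construction.

A cladogram here is a rooted tree whose leaves are in bijection with the
input set S and whose every node carries a sequence over the alphabet — not
necessarily one observed in S. Its parsimony length w(T) is the sum over
edges of the distance between the sequences labeling the edge's endpoints.

The central construction converts a minimum spanning tree T1 of the complete
distance graph into a cladogram T2 of the same total weight: the MST is
peeled leaf layer by leaf layer; each peeled vertex attaches below its
predecessor's internal copy, and every predecessor receives a zero-weight
pendant leaf carrying its own sequence, so all and only the elements of S
end up as leaves while every MST edge appears exactly once. Zero-weight
pendants contribute nothing, hence w(T2) = w(T1).
"""

from __future__ import annotations

from typing import Iterator, Optional

from .distances import Metric, get_metric, hamming_distance
from .errors import LabelingError
from .seqio import SequenceSet
from .spanning import SpanningTree


class Node:
    """A tree node: name, optional sequence label, optional explicit length."""

    __slots__ = ("name", "label", "children", "parent", "length")

    def __init__(
        self,
        name: str,
        label: Optional[str] = None,
        length: Optional[float] = None,
    ) -> None:
        self.name = name
        self.label = label
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.length = length

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def edge_length(self, metric: Metric) -> Optional[float]:
        """Length of the edge to the parent: explicit if set, else the
        metric distance between the two labels; None at the root."""
        if self.parent is None:
            return None
        if self.length is not None:
            return self.length
        if self.label is not None and self.parent.label is not None:
            return metric(self.label, self.parent.label)
        return None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal[{len(self.children)}]"
        return f"<Node {self.name} {kind} label={self.label!r}>"


class Cladogram:
    """A rooted tree with sequence labels and a distance metric."""

    def __init__(self, root: Node, metric: str | Metric = "hamming") -> None:
        self.root = root
        self.metric = get_metric(metric)

    def nodes(self) -> Iterator[Node]:
        """Preorder traversal."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.nodes())
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.nodes() if n.is_leaf]

    def edges(self) -> Iterator[tuple[Node, Node]]:
        for node in self.nodes():
            for child in node.children:
                yield node, child

    def leaf_map(self) -> dict[str, Node]:
        return {leaf.name: leaf for leaf in self.leaves()}

    def copy(self) -> "Cladogram":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.label, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Cladogram(clone(self.root), self.metric)


def from_nested(nested, metric: str | Metric = "hamming") -> Cladogram:
    """Build an unlabeled topology from nested tuples of leaf names.

    ``(("a", "b"), "c")`` gives a root with a cherry (a, b) and leaf c.
    Internal nodes get synthesized names n1, n2, ...
    """
    counter = [0]

    def build(part) -> Node:
        if isinstance(part, str):
            return Node(part)
        counter[0] += 1
        node = Node(f"n{counter[0]}")
        for sub in part:
            node.add_child(build(sub))
        return node

    return Cladogram(build(nested), metric)


def parsimony_weight(T: Cladogram, metric: str | Metric | None = None) -> float:
    """Parsimony length w(T): sum over edges of d(label(x), label(y))."""
    fn = T.metric if metric is None else get_metric(metric)
    total = 0
    for parent, child in T.edges():
        if parent.label is None or child.label is None:
            missing = child.name if child.label is None else parent.name
            raise LabelingError(f"node {missing!r} has no sequence label")
        total += fn(parent.label, child.label)
    return total


def mst_to_cladogram(
    T1: SpanningTree,
    S: Optional[SequenceSet] = None,
    metric: str | Metric = "hamming",
) -> Cladogram:
    """Convert a minimum spanning tree into a cladogram of equal weight.

    Vertices are peeled in leaf layers under the spanning tree's root
    orientation (the root is never peeled, so the terminal two-leaf case is
    subsumed by the generic step). Each predecessor vertex v gains an
    internal copy with a zero-weight pendant leaf (v, v, 0), created at most
    once, so the leaf set of the result is exactly the vertex set of T1.

    ``S`` supplies the sequence labels; when omitted, vertex ids are assumed
    to *be* the sequences (as in the small worked examples).
    """
    seq_of = (lambda v: S.seq_of(v)) if S is not None else (lambda v: v)
    vertices = sorted(T1.vertices)
    if len(vertices) == 1:
        only = vertices[0]
        return Cladogram(Node(only, label=seq_of(only)), metric)

    adj: dict[str, set[str]] = {v: set(T1.graph[v]) for v in vertices}
    internal: dict[str, Node] = {}

    def internal_copy(v: str) -> Node:
        if v not in internal:
            node = Node(v, label=seq_of(v))
            pendant = Node(v, label=seq_of(v), length=0)
            node.add_child(pendant)
            internal[v] = node
        return internal[v]

    remaining = sum(len(nb) for nb in adj.values()) // 2
    while remaining:
        layer = [v for v in vertices if v != T1.root and len(adj[v]) == 1]
        for u in layer:
            (p,) = adj[u]
            pnode = internal_copy(p)
            child = internal.get(u) or Node(u, label=seq_of(u))
            child.length = T1.graph[u][p]["weight"]
            pnode.add_child(child)
            adj[u].discard(p)
            adj[p].discard(u)
            remaining -= 1

    return Cladogram(internal[T1.root], metric)


def validate_cladogram(T: Cladogram, S: SequenceSet) -> list[str]:
    """Check the cladogram invariants against S; returns violations."""
    problems: list[str] = []
    leaf_names = [leaf.name for leaf in T.leaves()]
    if len(leaf_names) != len(set(leaf_names)):
        problems.append("duplicate leaf names")
    missing = set(S.ids) - set(leaf_names)
    extra = set(leaf_names) - set(S.ids)
    if missing:
        problems.append(f"leaves missing from tree: {sorted(missing)}")
    if extra:
        problems.append(f"leaves not in S: {sorted(extra)}")
    for node in T.nodes():
        if node.label is None:
            problems.append(f"node {node.name!r} is unlabeled")
        elif len(node.label) != S.n:
            problems.append(
                f"label of {node.name!r} has length {len(node.label)}, "
                f"expected {S.n}"
            )
        elif set(node.label) - set(S.alphabet):
            problems.append(f"label of {node.name!r} leaves the alphabet")
        if node.is_leaf and node.name in set(S.ids):
            if node.label is not None and node.label != S.seq_of(node.name):
                problems.append(
                    f"leaf {node.name!r} label differs from its sequence in S"
                )
        for child in node.children:
            if child.parent is not node:
                problems.append(f"broken parent link at {child.name!r}")
    return problems


__all__ = [
    "Node",
    "Cladogram",
    "from_nested",
    "parsimony_weight",
    "mst_to_cladogram",
    "validate_cladogram",
    "hamming_distance",
]
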