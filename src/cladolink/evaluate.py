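"""Flat clusterings from trees, and F-score comparison of clusterings.

A clustering is extracted from a dendrogram either by a height threshold
(join everything merged at height <= t; equivalently, connected components
of the minimum spanning tree after deleting edges heavier than t) or by a
cluster count (undo the last k-1 merges). A cladogram is truncated by
removing its k-1 heaviest edges (or, alternatively, all edges crossing a
given depth from the root).

Two clusterings of the same items are compared by F-score. The default
"pairwise" variant is the pair-counting F1: over all unordered item pairs,
precision and recall of "co-clustered in A" against "co-clustered in B";
it is symmetric and equals 1 exactly when the partitions coincide. The
"matching" variant is the cluster-matching F-measure
sum_i (|c_i|/N) * max_j F1(c_i, c'_j), symmetrized by averaging the two
directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .cladogram import Cladogram
from .linkage import Dendrogram


@dataclass(frozen=True)
class Clustering:
    """A partition of ids into clusters indexed contiguously from 0."""

    assignment: dict[str, int]

    def __post_init__(self) -> None:
        seen = sorted(set(self.assignment.values()))
        if seen != list(range(len(seen))):
            raise ValueError("cluster indices must be contiguous from 0")

    @property
    def k(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(self.assignment)

    def clusters(self) -> list[frozenset[str]]:
        out: dict[int, set[str]] = {}
        for rid, c in self.assignment.items():
            out.setdefault(c, set()).add(rid)
        return [frozenset(out[c]) for c in sorted(out)]


def _from_groups(ids: list[str], groups: list[set[str]]) -> Clustering:
    """Clustering with indices ordered by first appearance in ``ids``."""
    order: dict[frozenset, int] = {}
    lookup = {rid: frozenset(g) for g in groups for rid in g}
    assignment = {}
    for rid in ids:
        g = lookup[rid]
        if g not in order:
            order[g] = len(order)
        assignment[rid] = order[g]
    return Clustering(assignment)


def cut_by_threshold(dend: Dendrogram, t: float) -> Clustering:
    """Join everything connected by merges at height <= t."""
    n = len(dend.ids)
    groups: dict[int, set[str]] = {i: {rid} for i, rid in enumerate(dend.ids)}
    for step, m in enumerate(dend.merges):
        if m.height <= t:
            groups[n + step] = groups.pop(m.a) | groups.pop(m.b)
        else:
            groups[n + step] = set()  # later merges are at least as high
    return _from_groups(list(dend.ids), [g for g in groups.values() if g])


def _cut_dendrogram_by_count(dend: Dendrogram, k: int) -> Clustering:
    n = len(dend.ids)
    groups: dict[int, set[str]] = {i: {rid} for i, rid in enumerate(dend.ids)}
    for step in range(n - k):
        m = dend.merges[step]
        groups[n + step] = groups.pop(m.a) | groups.pop(m.b)
    return _from_groups(list(dend.ids), list(groups.values()))


def _cut_cladogram_by_count(tree: Cladogram, k: int) -> Clustering:
    """Remove the k-1 heaviest edges (ties broken by the child's subtree
    name set) and cluster leaves by remaining component."""
    edges = []
    for parent, child in tree.edges():
        w = child.edge_length(tree.metric)
        if w is None:
            raise ValueError("cladogram edges need labels or explicit lengths")
        edges.append((w, min(leaf.name for leaf in _subtree_leaves(child)), child))
    edges.sort(key=lambda e: (-e[0], e[1]))
    cut_children = {id(child) for _, _, child in edges[: k - 1]}

    leaf_order = [leaf.name for leaf in tree.leaves()]
    groups: list[set[str]] = []

    def collect(node, bucket: set[str]) -> None:
        if node.is_leaf:
            bucket.add(node.name)
        for child in node.children:
            if id(child) in cut_children:
                fresh: set[str] = set()
                groups.append(fresh)
                collect(child, fresh)
            else:
                collect(child, bucket)

    top: set[str] = set()
    groups.append(top)
    collect(tree.root, top)
    nonempty = [g for g in groups if g]
    if len(nonempty) != k:
        warnings.warn(
            f"requested {k} clusters, tree structure yields {len(nonempty)}",
            stacklevel=2,
        )
    return _from_groups(leaf_order, nonempty)


def _subtree_leaves(node):
    stack = [node]
    while stack:
        cur = stack.pop()
        if cur.is_leaf:
            yield cur
        stack.extend(cur.children)


def cut_by_count(tree: Dendrogram | Cladogram, k: int) -> Clustering:
    """Truncate a tree into (as close as achievable to) k clusters."""
    size = len(tree.ids) if isinstance(tree, Dendrogram) else len(tree.leaves())
    if not 1 <= k <= size:
        raise ValueError(f"k must be in 1..{size}, got {k}")
    if isinstance(tree, Dendrogram):
        return _cut_dendrogram_by_count(tree, k)
    return _cut_cladogram_by_count(tree, k)


def cut_cladogram_by_depth(tree: Cladogram, depth: float) -> Clustering:
    """Alternative cladogram truncation: cut every edge whose span of
    cumulative root distance crosses ``depth``."""
    dist = {id(tree.root): 0.0}
    cut = set()
    for parent, child in tree.edges():
        w = child.edge_length(tree.metric) or 0.0
        dist[id(child)] = dist[id(parent)] + w
        if dist[id(parent)] <= depth < dist[id(child)]:
            cut.add(id(child))

    groups: list[set[str]] = []

    def collect(node, bucket):
        if node.is_leaf:
            bucket.add(node.name)
        for child in node.children:
            if id(child) in cut:
                fresh: set[str] = set()
                groups.append(fresh)
                collect(child, fresh)
            else:
                collect(child, bucket)

    top: set[str] = set()
    groups.append(top)
    collect(tree.root, top)
    return _from_groups(
        [leaf.name for leaf in tree.leaves()], [g for g in groups if g]
    )


def _co_clustered_pairs(C: Clustering) -> set[frozenset[str]]:
    pairs = set()
    for cluster in C.clusters():
        members = sorted(cluster)
        for i, x in enumerate(members):
            for y in members[i + 1 :]:
                pairs.add(frozenset((x, y)))
    return pairs


def _f1(x: frozenset[str], y: frozenset[str]) -> float:
    inter = len(x & y)
    return 2 * inter / (len(x) + len(y)) if inter else 0.0


def fscore(A: Clustering, B: Clustering, variant: str = "pairwise") -> float:
    """Agreement between two partitions of the same items, in [0, 1]."""
    if A.ids != B.ids:
        raise ValueError("clusterings cover different id sets")
    if variant == "pairwise":
        pa, pb = _co_clustered_pairs(A), _co_clustered_pairs(B)
        if not pa and not pb:  # both all-singletons: identical partitions
            return 1.0
        return 2 * len(pa & pb) / (len(pa) + len(pb))
    if variant == "matching":
        n = len(A.ids)

        def one_way(X: Clustering, Y: Clustering) -> float:
            return sum(
                len(c) / n * max(_f1(c, c2) for c2 in Y.clusters())
                for c in X.clusters()
            )

        return (one_way(A, B) + one_way(B, A)) / 2
    raise ValueError(f"unknown F-score variant {variant!r}")


def comparison_report(
    clusterings: dict[str, Clustering], variant: str = "pairwise"
) -> dict[str, dict[str, float]]:
    """Pairwise F-score matrix over named clusterings (unit diagonal)."""
    names = list(clusterings)
    return {
        a: {b: fscore(clusterings[a], clusterings[b], variant) for b in names}
        for a in names
    }
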