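"""Single-linkage agglomerative clustering, plain and label-assigning.

Two variants share one agglomeration core. The standard variant records the
merge history (a dendrogram). The modified variant additionally assigns to
every internal node a sequence drawn from S itself: when clusters Ci and Cj
merge, the member pair (x in Ci, y in Cj) realizing the single-linkage
minimum d(x, y) provides the labels — a singleton cluster keeps its own
point, a composite cluster is labeled by its member of that pair. The result
is a cladogram with all labels in S, so its parsimony weight is defined,
though nothing guarantees it matches the minimum spanning tree weight (and
for some inputs no labeling of this topology can).

Ties (between cluster pairs at equal linkage distance, and between member
pairs at equal distance) are broken by the lexicographically smallest sorted
id pair, making the output deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .cladogram import Cladogram, Node
from .distances import DistanceMatrix, Metric, distance_matrix
from .seqio import SequenceSet


@dataclass(frozen=True)
class Merge:
    """One agglomeration step in the linkage-matrix convention.

    ``a`` and ``b`` index the merged clusters (original points 0..n-1, the
    i-th newly formed cluster n+i); ``pair`` is the member pair (one id from
    each side, a-side first) that realized the single-linkage distance.
    """

    a: int
    b: int
    height: float
    size: int
    pair: Optional[tuple[str, str]] = None


@dataclass(frozen=True)
class Dendrogram:
    """Merge history of an agglomerative clustering over ``ids``."""

    ids: tuple[str, ...]
    merges: tuple[Merge, ...]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.ids) - 1:
            raise ValueError("a dendrogram needs exactly |S| - 1 merges")
        h = self.heights
        if any(h[i] > h[i + 1] for i in range(len(h) - 1)):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def heights(self) -> list[float]:
        return [m.height for m in self.merges]

    def to_scipy(self) -> np.ndarray:
        """The merge history as a (|S|-1, 4) scipy-style linkage matrix."""
        return np.array(
            [[m.a, m.b, m.height, m.size] for m in self.merges], dtype=float
        )

    def as_cladogram(self) -> Cladogram:
        """The merge tree with explicit branch lengths (height drops);
        nodes are unlabeled — topology and heights only."""
        n = len(self.ids)
        height: dict[int, float] = {i: 0.0 for i in range(n)}
        nodes: dict[int, Node] = {i: Node(rid) for i, rid in enumerate(self.ids)}
        for t, m in enumerate(self.merges):
            new = Node(f"m{t + 1}")
            for c in (m.a, m.b):
                child = nodes[c]
                child.length = m.height - height[c]
                new.add_child(child)
            nodes[n + t] = new
            height[n + t] = m.height
        root = nodes[n + len(self.merges) - 1]
        root.length = None
        return Cladogram(root)


@dataclass(frozen=True)
class LabeledLinkageTree:
    """The label-assigning variant's output: a cladogram whose topology is
    the single-linkage merge tree and whose labels all lie in S, plus the
    dendrogram and the provenance of every label choice."""

    tree: Cladogram
    dendrogram: Dendrogram
    provenance: tuple[tuple[str, str], ...] = field(default_factory=tuple)


def _agglomerate(D: DistanceMatrix) -> list[Merge]:
    """Single-linkage agglomeration with deterministic tie-breaking."""
    ids = list(D.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("clustering needs at least two sequences")
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges: list[Merge] = []
    for step in range(n - 1):
        best = None  # (dist, sorted id pair, ci, cj, a-side id, b-side id)
        active = sorted(members)
        for u, ci in enumerate(active):
            for cj in active[u + 1 :]:
                mi, mj = members[ci], members[cj]
                sub = D.values[np.ix_(mi, mj)]
                dist = sub.min()
                # among member pairs at this distance, smallest sorted id pair
                pair = min(
                    (tuple(sorted((ids[mi[i]], ids[mj[j]]))), ids[mi[i]], ids[mj[j]])
                    for i, j in zip(*np.nonzero(sub == dist))
                )
                key = (dist, pair[0])
                if best is None or key < best[0]:
                    best = (key, ci, cj, pair[1], pair[2])
        (dist, _), ci, cj, xa, yb = best
        a, b = sorted((ci, cj))
        pair = (xa, yb) if a == ci else (yb, xa)
        members[n + step] = members.pop(ci) + members.pop(cj)
        merges.append(
            Merge(a, b, float(dist), len(members[n + step]), pair)
        )
    return merges


def single_linkage(D: DistanceMatrix) -> Dendrogram:
    """Standard single-linkage hierarchical clustering of a distance matrix."""
    return Dendrogram(tuple(D.ids), tuple(_agglomerate(D)))


def normalize_heights(dend: Dendrogram, n: int) -> Dendrogram:
    """Divide every merge height by the sequence length ``n``."""
    if n < 1:
        raise ValueError("sequence length must be >= 1")
    return Dendrogram(
        dend.ids,
        tuple(replace(m, height=m.height / n) for m in dend.merges),
    )


def merge_tree(dend: Dendrogram) -> Cladogram:
    """The bare merge-tree topology (no labels, no lengths) of a dendrogram,
    suitable as a fixed topology for small-parsimony labeling."""
    tree = dend.as_cladogram()
    for node in tree.nodes():
        node.length = None
    return tree


def labeled_single_linkage(
    S: SequenceSet, metric: str | Metric = "hamming"
) -> LabeledLinkageTree:
    """Single-linkage clustering that also labels internal nodes from S.

    The final cluster is never merged into anything, so the loop leaves the
    root unlabeled; the root inherits the label of its larger child (its
    label id breaking ties lexicographically), recorded in provenance under
    the pseudo-id "root".
    """
    D = distance_matrix(S, metric)
    merges = _agglomerate(D)
    n = len(S)
    nodes: dict[int, Node] = {
        i: Node(rid, label=S.seq_of(rid)) for i, rid in enumerate(S.ids)
    }
    label_id: dict[int, str] = {i: rid for i, rid in enumerate(S.ids)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    provenance: list[tuple[str, str]] = []
    for t, m in enumerate(merges):
        xa, yb = m.pair
        for c, member in ((m.a, xa), (m.b, yb)):
            if c >= n:  # composite cluster: labeled by its argmin member
                nodes[c].label = S.seq_of(member)
                label_id[c] = member
                provenance.append((nodes[c].name, member))
        new = Node(f"m{t + 1}")
        new.add_child(nodes[m.a])
        new.add_child(nodes[m.b])
        nodes[n + t] = new
        sizes[n + t] = m.size
    root_idx = n + len(merges) - 1
    root = nodes[root_idx]
    last = merges[-1]
    chosen = min(
        (last.a, last.b), key=lambda c: (-sizes[c], label_id[c])
    )
    root.label = nodes[chosen].label
    label_id[root_idx] = label_id[chosen]
    provenance.append(("root", label_id[chosen]))
    return LabeledLinkageTree(
        Cladogram(root, metric),
        Dendrogram(tuple(S.ids), tuple(merges)),
        tuple(provenance),
    )
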