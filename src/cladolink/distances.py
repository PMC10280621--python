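"""Pairwise sequence distances and the complete weighted graph G(S).

The package works with any function satisfying the three distance axioms
(non-negativity with identity of indiscernibles, symmetry, triangle
inequality); the default is the Hamming distance, which counts the positions
at which two equal-length sequences differ. Hamming values are kept as exact
integers so that tie-breaking never suffers float drift; normalized values
are computed on demand and never stored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import networkx as nx
import numpy as np

from .errors import MetricError
from .seqio import SequenceSet

Metric = Callable[[str, str], float]


def hamming_distance(x: str, y: str) -> int:
    """Number of positions at which ``x`` and ``y`` differ."""
    if len(x) != len(y):
        raise ValueError(
            f"hamming_distance needs equal lengths, got {len(x)} and {len(y)}"
        )
    return sum(a != b for a, b in zip(x, y))


METRICS: dict[str, Metric] = {"hamming": hamming_distance}


def get_metric(metric: str | Metric) -> Metric:
    """Resolve a metric by registry name, or pass a callable through."""
    if callable(metric):
        return metric
    try:
        return METRICS[metric]
    except KeyError:
        raise MetricError(
            f"unknown metric {metric!r}; registered: {sorted(METRICS)}"
        ) from None


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise distances, rows ordered as the ids."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if (v < 0).any() or (np.diag(v) != 0).any() or not (v == v.T).all():
            raise ValueError("distance matrix must be symmetric, "
                             "non-negative, with zero diagonal")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return self.values[i, j]


def distance_matrix(S: SequenceSet, metric: str | Metric = "hamming") -> DistanceMatrix:
    """All pairwise distances over S, in record order."""
    if metric == "hamming" or metric is hamming_distance:
        # vectorized: compare byte arrays site by site
        arr = np.frombuffer(
            "".join(S.seqs).encode(), dtype=np.uint8
        ).reshape(len(S), S.n)
        values = (arr[:, None, :] != arr[None, :, :]).sum(axis=2).astype(np.int64)
    else:
        fn = get_metric(metric)
        m = len(S)
        values = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                values[i, j] = values[j, i] = fn(S.seqs[i], S.seqs[j])
    return DistanceMatrix(tuple(S.ids), values)


def complete_graph(S: SequenceSet, metric: str | Metric = "hamming") -> nx.Graph:
    """The complete graph G(S): one vertex per record id, edge weights d(x, y)."""
    D = distance_matrix(S, metric)
    G = nx.Graph()
    G.add_nodes_from(D.ids)
    for i, u in enumerate(D.ids):
        for j in range(i + 1, len(D.ids)):
            G.add_edge(u, D.ids[j], weight=D.values[i, j].item())
    return G
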