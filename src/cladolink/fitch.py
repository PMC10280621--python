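"""Small parsimony: optimal internal labeling of a fixed leaf-labeled tree.

Characters are unordered, multistate and reversible, so under the Hamming
distance the problem decomposes exactly per site. Each site is solved by
uniform-cost dynamic programming (cost 0 for keeping a state along an edge,
1 for changing it), the multifurcation-safe generalization of the classical
two-pass set algorithm to which it reduces on binary nodes:

    cost(v, s) = sum over children c of  min_{s'} [ cost(c, s') + 1_{s' != s} ]
               = sum over children c of  min( cost(c, s), min_{s'} cost(c, s') + 1 )

and the per-site minimum number of changes is min_s cost(root, s). All sites
are processed at once as (states x sites) integer matrices.

The traceback resolving one optimal labeling is deterministic: the root
takes the lexicographically smallest optimal state, and every other node
keeps its parent's state whenever that is optimal, falling back to the
lexicographically smallest optimal state otherwise.
"""

from __future__ import annotations

import numpy as np

from .cladogram import Cladogram, Node
from .errors import LabelingError
from .seqio import SequenceSet

_BIG = np.int64(1) << 40  # effectively infinite edge cost


def _leaf_sequences(topology: Cladogram, S: SequenceSet) -> dict[str, str]:
    seqs = {}
    ids = set(S.ids)
    for leaf in topology.leaves():
        if leaf.name not in ids:
            raise LabelingError(
                f"leaf {leaf.name!r} has no sequence in S"
            )
        seqs[leaf.name] = S.seq_of(leaf.name)
    if len(seqs) != len(S):
        missing = ids - set(seqs)
        raise LabelingError(f"sequences of S missing from topology: {sorted(missing)}")
    return seqs


def _cost_tables(
    topology: Cladogram, S: SequenceSet
) -> tuple[list[str], dict[Node, np.ndarray]]:
    """Bottom-up DP: per node a (|alphabet| x n) matrix of minimal costs."""
    alphabet = sorted(S.alphabet)
    index = {s: i for i, s in enumerate(alphabet)}
    leaf_seq = _leaf_sequences(topology, S)
    cost: dict[Node, np.ndarray] = {}
    for node in topology.postorder():
        if node.is_leaf:
            c = np.full((len(alphabet), S.n), _BIG, dtype=np.int64)
            cols = np.arange(S.n)
            rows = np.fromiter(
                (index[sym] for sym in leaf_seq[node.name]), dtype=np.int64
            )
            c[rows, cols] = 0
        else:
            c = np.zeros((len(alphabet), S.n), dtype=np.int64)
            for child in node.children:
                cc = cost[child]
                c += np.minimum(cc, cc.min(axis=0)[None, :] + 1)
        cost[node] = c
    return alphabet, cost


def fitch_min_weight(topology: Cladogram, S: SequenceSet) -> int:
    """Minimum parsimony weight over all internal labelings of ``topology``.

    Equals the exhaustive minimum over every assignment of alphabet
    sequences to internal nodes; the per-site decomposition is exact for the
    Hamming distance.
    """
    if len(topology.leaves()) == 1:
        _leaf_sequences(topology, S)
        return 0
    _, cost = _cost_tables(topology, S)
    return int(cost[topology.root].min(axis=0).sum())


def fitch_label(topology: Cladogram, S: SequenceSet) -> Cladogram:
    """A fully labeled copy of ``topology`` achieving :func:`fitch_min_weight`."""
    out = topology.copy()
    leaf_seq = _leaf_sequences(out, S)
    for leaf in out.leaves():
        leaf.label = leaf_seq[leaf.name]
    if len(out.leaves()) == 1:
        return out

    alphabet, cost = _cost_tables(out, S)
    symbols = np.array(alphabet)
    states: dict[Node, np.ndarray] = {}
    for node in out.nodes():  # preorder: parents before children
        c = cost[node]
        best = c.argmin(axis=0)  # argmin takes the first = smallest index
        if node.parent is None:
            choice = best
        else:
            ps = states[node.parent]
            # keep the parent's state wherever it is optimal for this subtree
            keep = c[ps, np.arange(c.shape[1])] <= c.min(axis=0) + 1
            choice = np.where(keep, ps, best)
        states[node] = choice
        node.label = "".join(symbols[choice])
        node.length = None  # lengths now follow from the labels
    return out
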