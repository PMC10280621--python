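"""Brute-force ground truth at desk scale.

The large-parsimony problem is NP-complete, so exhaustive search is only
usable on tiny inputs — which is exactly what makes it a trustworthy oracle
for the polynomial-time constructions elsewhere in the package. Rooted
binary topologies are enumerated by stepwise leaf addition ((2m-3)!! trees
for m leaves); per fixed topology the optimal internal labeling is found by
the exact small-parsimony DP. Restricting to binary topologies loses
nothing: contracting an edge never lowers the weight, so a multifurcating
optimum is matched by a binary tree with a zero-cost edge.

``exhaustive_min_labeling`` additionally re-derives the small-parsimony
minimum by literal enumeration of internal-state assignments (per site,
which is exact under Hamming distance), providing an implementation-
independent check of the DP itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterator, Optional

from .cladogram import Cladogram, from_nested
from .fitch import fitch_label, fitch_min_weight
from .errors import SizeGuardError
from .seqio import SequenceSet

Nested = object  # leaf name (str) or tuple of two Nested


@dataclass(frozen=True)
class OracleResult:
    optimal_weight: int
    tree: Cladogram
    topologies_inspected: int


def _insertions(tree, leaf: str) -> Iterator[object]:
    """All ways to attach ``leaf`` to a rooted binary tree: above the root,
    or splitting any edge."""
    yield (tree, leaf)
    if isinstance(tree, tuple):
        left, right = tree
        for sub in _insertions(left, leaf):
            yield (sub, right)
        for sub in _insertions(right, leaf):
            yield (left, sub)


def enumerate_topologies(ids: list[str]) -> Iterator[object]:
    """All rooted binary leaf-labeled topologies on ``ids`` as nested tuples."""
    if len(ids) == 1:
        yield ids[0]
        return
    for smaller in enumerate_topologies(ids[:-1]):
        yield from _insertions(smaller, ids[-1])


def most_parsimonious_tree(S: SequenceSet, max_leaves: int = 8) -> OracleResult:
    """The global minimum of parsimony weight over all rooted binary
    topologies on S, with internal labels optimized per topology."""
    if len(S) > max_leaves:
        raise SizeGuardError(
            f"|S| = {len(S)} exceeds the brute-force bound {max_leaves}"
        )
    best_weight: Optional[int] = None
    best_topology = None
    count = 0
    for nested in enumerate_topologies(S.ids):
        count += 1
        tree = from_nested(nested)
        w = fitch_min_weight(tree, S)
        if best_weight is None or w < best_weight:
            best_weight, best_topology = w, nested
    labeled = fitch_label(from_nested(best_topology), S)
    return OracleResult(int(best_weight), labeled, count)


def exhaustive_min_labeling(
    topology: Cladogram,
    S: SequenceSet,
    alphabet: Optional[set[str]] = None,
    max_assignments: int = 1 << 24,
) -> int:
    """True minimum weight over every internal label assignment, by literal
    enumeration (per site, exact for Hamming distance)."""
    alpha = sorted(alphabet or S.alphabet)
    internal = [n for n in topology.nodes() if not n.is_leaf]
    per_site = len(alpha) ** len(internal)
    if per_site * S.n > max_assignments:
        raise SizeGuardError(
            f"{per_site} assignments per site x {S.n} sites exceeds "
            f"the enumeration bound {max_assignments}"
        )
    leaf_seq = {leaf.name: S.seq_of(leaf.name) for leaf in topology.leaves()}
    total = 0
    for site in range(S.n):
        state = {id(leaf): leaf_seq[leaf.name][site] for leaf in topology.leaves()}
        best = None
        for assignment in product(alpha, repeat=len(internal)):
            for node, s in zip(internal, assignment):
                state[id(node)] = s
            cost = sum(
                state[id(p)] != state[id(c)] for p, c in topology.edges()
            )
            if best is None or cost < best:
                best = cost
        total += best
    return total


def parsimony_lower_bound(S: SequenceSet) -> int:
    """Site-wise bound: sum over sites of (distinct observed states - 1).

    Any tree connecting S must change state at least that often, so the
    bound certifies oracle optima that attain it.
    """
    return sum(
        len({seq[site] for seq in S.seqs}) - 1 for site in range(S.n)
    )
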