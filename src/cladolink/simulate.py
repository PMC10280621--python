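"""Synthetic sequence sets: tree-evolved fixtures and adversarial instances.

``simulate_tree_sequences`` grows a random rooted binary topology by uniform
stepwise leaf addition, draws a root sequence uniformly over the alphabet,
and mutates each site independently along each edge with a fixed per-site
probability (a mutated site takes a uniformly chosen *different* symbol).
The generating tree is returned alongside the leaves; its parsimony weight
upper-bounds the optimal parsimony of the leaf set, which gives property
tests a free one-sided oracle. This emulates homoplasy-rich short
alignments; it does not model indels, rate heterogeneity or realistic
substitution processes, so conclusions about real data rest on the exact
worked examples and bounds, not on distributional realism.

``make_demarcation_instance`` builds the adversarial family on which
single-linkage merge order is provably incompatible with MST-level
parsimony: a chain of binary sequences descending by small Hamming steps
(ones-prefixes n_1 > ... > 1^2 0^.. > all-zeros) plus the all-ones outlier
at distance n from the all-zeros end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cladogram import Cladogram, Node
from .seqio import SequenceSet, sequence_set

DNA = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated alignment."""

    leaves: int
    n: int
    p: float = 0.1  # per-site substitution probability per edge
    alphabet: tuple[str, ...] = DNA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.leaves < 2 or self.n < 1:
            raise ValueError("need at least 2 leaves and 1 site")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("substitution probability must lie in [0, 1]")
        if len(self.alphabet) < 2:
            raise ValueError("alphabet needs at least two symbols")


def _random_topology(m: int, rng: np.random.Generator) -> Node:
    """Uniform stepwise addition: each new leaf splits a uniformly chosen
    edge or becomes a sibling of the whole tree."""
    root = Node("s1")
    for i in range(2, m + 1):
        leaf = Node(f"s{i}")
        edges: list[Node] = [n for n in _walk(root) if n.parent is not None]
        pick = rng.integers(len(edges) + 1)
        if pick == len(edges):  # new root above everything
            new_root = Node("")
            new_root.add_child(root)
            new_root.add_child(leaf)
            root = new_root
        else:
            child = edges[pick]
            parent = child.parent
            mid = Node("")
            parent.children[parent.children.index(child)] = mid
            mid.parent = parent
            mid.add_child(child)
            mid.add_child(leaf)
    k = 0
    for node in _walk(root):
        if not node.name:
            k += 1
            node.name = f"anc{k}"
    return root


def _walk(node: Node):
    stack = [node]
    while stack:
        cur = stack.pop()
        yield cur
        stack.extend(cur.children)


def simulate_tree_sequences(
    cfg: SimulationConfig,
) -> tuple[SequenceSet, Cladogram]:
    """Evolve sequences down a random tree; returns the leaf set and the
    fully labeled generating tree. Bit-for-bit reproducible per seed."""
    rng = np.random.default_rng(cfg.seed)
    alpha = np.array(cfg.alphabet)
    k = len(alpha)
    if cfg.leaves == 1:  # degenerate but allowed via direct construction
        raise ValueError("need at least 2 leaves")
    root = _random_topology(cfg.leaves, rng)

    root_states = rng.integers(k, size=cfg.n)
    states = {id(root): root_states}
    for node in _walk(root):
        if node.parent is None:
            continue
        parent_states = states[id(node.parent)]
        mutate = rng.random(cfg.n) < cfg.p
        shift = rng.integers(1, k, size=cfg.n)  # jump to a *different* symbol
        child_states = np.where(
            mutate, (parent_states + shift) % k, parent_states
        )
        states[id(node)] = child_states
    for node in _walk(root):
        node.label = "".join(alpha[states[id(node)]])

    tree = Cladogram(root)
    leaves = sorted(tree.leaves(), key=lambda lf: int(lf.name[1:]))
    S = sequence_set(
        [(leaf.name, leaf.label) for leaf in leaves], alphabet=cfg.alphabet
    )
    return S, tree


def make_demarcation_instance(chain_length: int, n: int) -> SequenceSet:
    """Chain-plus-outlier binary instance; (3, 7) reproduces the canonical
    four-sequence example {1111111, 1110000, 1100000, 0000000}."""
    if chain_length < 3:
        raise ValueError("chain_length must be >= 3")
    if n < chain_length + 2:
        raise ValueError("need n >= chain_length + 2 for a distant outlier")
    ones_counts = list(range(chain_length, 1, -1)) + [0]
    seqs = ["1" * n] + ["1" * c + "0" * (n - c) for c in ones_counts]
    return sequence_set(seqs, alphabet="01")
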