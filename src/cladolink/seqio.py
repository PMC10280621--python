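"""Input/output: FASTA in; Newick, linkage tables, distance matrices and
cluster assignments out.

Sequences are upper-cased on read so that Hamming comparisons are
case-insensitive. Gap and ambiguity symbols ('-', 'N', ...) are ordinary
alphabet states: they count as mismatches against any other state, matching
the unordered multistate character model used throughout the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Union

from Bio import SeqIO

from .errors import AlignmentError, AlphabetError, FormatError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for type hints
    from .cladogram import Cladogram
    from .linkage import Dendrogram


@dataclass(frozen=True)
class SequenceRecord:
    """A single named sequence over a finite alphabet."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record has an empty id")
        if not self.seq:
            raise FormatError(f"record {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class SequenceSet:
    """An ordered set S of equal-length sequences with its alphabet.

    ``n`` is the shared sequence length (number of sites); ``alphabet`` is the
    finite symbol set over which all sequences — observed or hypothetical
    internal labels — are drawn.
    """

    records: tuple[SequenceRecord, ...]
    alphabet: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError("SequenceSet needs at least one record")
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) > 1:
            raise AlignmentError(
                f"sequences are not aligned: lengths {sorted(lengths)}"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate sequence ids: {dupes}")
        alphabet = self.alphabet or frozenset(
            sym for r in self.records for sym in r.seq
        )
        object.__setattr__(self, "alphabet", frozenset(alphabet))
        bad = {
            (r.id, sym)
            for r in self.records
            for sym in set(r.seq) - self.alphabet
        }
        if bad:
            raise AlphabetError(
                f"symbols outside declared alphabet {sorted(self.alphabet)}: "
                f"{sorted(bad)}"
            )

    @property
    def n(self) -> int:
        """Sequence length (number of sites)."""
        return len(self.records[0].seq)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def seqs(self) -> list[str]:
        return [r.seq for r in self.records]

    def seq_of(self, record_id: str) -> str:
        for r in self.records:
            if r.id == record_id:
                return r.seq
        raise KeyError(record_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def sequence_set(
    pairs: Iterable[tuple[str, str]] | Iterable[str],
    alphabet: Union[Iterable[str], str] = "infer",
) -> SequenceSet:
    """Build a SequenceSet from (id, seq) pairs, or from bare sequences
    (which then serve as their own ids)."""
    items = list(pairs)
    if items and isinstance(items[0], str):
        items = [(s, s) for s in items]
    records = tuple(SequenceRecord(i, s.upper()) for i, s in items)
    alpha = frozenset() if alphabet == "infer" else frozenset(
        a.upper() for a in alphabet
    )
    return SequenceSet(records, alpha)


def read_fasta(
    path: str | Path, alphabet: Union[Iterable[str], str] = "infer"
) -> SequenceSet:
    """Read an aligned FASTA file into a SequenceSet.

    Sequences are upper-cased; ``alphabet="infer"`` takes the symbol set
    observed in the file. Raises :class:`AlignmentError` on unequal lengths,
    :class:`FormatError` on duplicate ids and :class:`AlphabetError` when a
    symbol falls outside a declared alphabet.
    """
    path = Path(path)
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return sequence_set(records, alphabet)


def write_fasta(S: SequenceSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in S:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


_NEWICK_UNSAFE = re.compile(r"[\s()\[\]{}:;,'\"]")


def _newick_name(name: str) -> str:
    if _NEWICK_UNSAFE.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def newick_string(
    tree: Union["Cladogram", "Dendrogram"], normalize_by: int | None = None
) -> str:
    """Render a cladogram or dendrogram as a Newick string.

    Branch lengths are the edge distance contributions: for a cladogram the
    metric distance between the labels of the edge endpoints, for a dendrogram
    the drop from the parent merge height. ``normalize_by`` divides all
    lengths by the sequence length n.
    """
    from .cladogram import Cladogram  # local import to avoid a cycle
    from .linkage import Dendrogram

    scale = 1.0 / normalize_by if normalize_by else 1.0

    if isinstance(tree, Dendrogram):
        tree = tree.as_cladogram()
    if not isinstance(tree, Cladogram):
        raise TypeError(f"cannot render {type(tree).__name__} as Newick")

    def render(node) -> str:
        name = _newick_name(node.name)
        length = node.edge_length(tree.metric)
        suffix = "" if length is None else f":{length * scale:g}"
        if not node.children:
            return f"{name}{suffix}"
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}){name}{suffix}"

    return render(tree.root) + ";"


def write_newick(
    tree: Union["Cladogram", "Dendrogram"],
    path: str | Path,
    normalize_by: int | None = None,
) -> None:
    """Write a tree to ``path`` in Newick format (see :func:`newick_string`)."""
    with open(path, "w") as fh:
        fh.write(newick_string(tree, normalize_by=normalize_by) + "\n")


def read_newick(path: str | Path) -> "Cladogram":
    """Read a rooted Newick tree into an (unlabeled) Cladogram topology.

    Node names and branch lengths are preserved; unnamed internal nodes get
    synthesized names n1, n2, ... Sequence labels are not part of Newick and
    are left unset — attach them from a SequenceSet by node name.
    """
    from Bio import Phylo

    from .cladogram import Cladogram, Node

    clade_tree = Phylo.read(str(path), "newick")

    def convert(clade) -> Node:
        node = Node(clade.name or "", length=clade.branch_length)
        for sub in clade.clades:
            node.add_child(convert(sub))
        return node

    root = convert(clade_tree.root)
    tree = Cladogram(root)
    counter = 0
    for node in tree.nodes():
        if not node.name:
            counter += 1
            node.name = f"n{counter}"
    return tree


def write_linkage_table(dendrogram: "Dendrogram", path: str | Path) -> None:
    """Write the merge history as a TSV linkage table.

    One row per merge, |S|-1 rows total, columns cluster_a / cluster_b /
    height / size in the widely used linkage-matrix convention: original
    points are indexed 0..|S|-1 and the i-th newly created cluster |S|+i.
    """
    with open(path, "w") as fh:
        fh.write("cluster_a\tcluster_b\theight\tsize\n")
        for m in dendrogram.merges:
            fh.write(f"{m.a}\t{m.b}\t{m.height:g}\t{m.size}\n")


def write_distance_matrix(D, path: str | Path) -> None:
    """Write a DistanceMatrix as TSV with an id header row and column."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(D.ids) + "\n")
        for i, rid in enumerate(D.ids):
            row = "\t".join(f"{v:g}" for v in D.values[i])
            fh.write(f"{rid}\t{row}\n")


def write_clusters(clustering, path: str | Path) -> None:
    """Write a Clustering as a two-column id -> cluster-index TSV."""
    with open(path, "w") as fh:
        fh.write("id\tcluster\n")
        for rid, c in clustering.assignment.items():
            fh.write(f"{rid}\t{c}\n")
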