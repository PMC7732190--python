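"""Trees, amino-acid alignments, splits, and the file formats that carry them.

Trees are stored rooted for convenience but carry unrooted semantics
throughout: under time-reversible models the likelihood does not depend on
root placement, and all split/monophyly operations work on bipartitions of
the leaf set.

The amino-acid alphabet is fixed to the order ``ARNDCQEGHILKMFPSTWYV``
(codes 0-19); code 20 stands for gap/unknown and is treated as fully
missing data by the likelihood machinery.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
GAP_CODE = 20

_ENCODE = np.full(256, GAP_CODE, dtype=np.uint8)
for _i, _aa in enumerate(AA_ORDER):
    _ENCODE[ord(_aa)] = _i
    _ENCODE[ord(_aa.lower())] = _i

_DECODE = np.array(list(AA_ORDER + "-"), dtype="U1")


class TreeError(ValueError):
    """Malformed tree input or an operation violating tree preconditions."""


class AlignmentError(ValueError):
    """Malformed alignment input or inconsistent taxa."""


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


class Node:
    """A tree node; ``length`` is the branch to the parent (substitutions/site)."""

    __slots__ = ("name", "length", "children")

    def __init__(self, name=None, length=0.0, children=None):
        self.name = name
        self.length = float(length)
        self.children: list[Node] = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        return Node(self.name, self.length,
                    [c.copy() for c in self.children])


class Tree:
    """Leaf-labeled tree with non-negative branch lengths, unrooted semantics.

    ``clades`` optionally maps clade names to frozensets of leaf labels and
    is carried along by generators and experiments.
    """

    def __init__(self, root: Node, clades: dict[str, frozenset] | None = None):
        self.root = root
        self.clades: dict[str, frozenset] = dict(clades or {})

    # -- traversal ---------------------------------------------------------

    def postorder(self):
        stack, out = [self.root], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def copy(self) -> "Tree":
        return Tree(self.root.copy(), dict(self.clades))

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n is not self.root)

    # -- newick ------------------------------------------------------------

    def newick(self) -> str:
        return write_newick(self)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tree({self.newick()!r})"


def _resolve_polytomy(node: Node) -> None:
    while len(node.children) > 2:
        a = node.children.pop()
        b = node.children.pop()
        node.children.append(Node(None, 0.0, [b, a]))


def parse_newick(text: str, resolve_polytomies: bool = False) -> Tree:
    """Parse a newick string into a :class:`Tree`.

    Branch lengths default to 0 when absent.  Internal nodes must be binary
    (the root may be trifurcating, the usual unrooted convention); other
    multifurcations raise :class:`TreeError` unless ``resolve_polytomies``
    is set, in which case they are resolved arbitrarily with zero-length
    branches.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy reports the offending position
        raise TreeError(f"malformed newick: {exc}") from exc

    def convert(dnode) -> Node:
        name = None
        if dnode.taxon is not None:
            name = dnode.taxon.label
        elif dnode.label:
            name = dnode.label
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        if length < 0:
            raise TreeError(f"negative branch length {length}")
        node = Node(name, length, [convert(c) for c in dnode.child_nodes()])
        if len(node.children) == 1:
            raise TreeError("unifurcation in newick input")
        return node

    root = convert(dtree.seed_node)
    root.length = 0.0
    tree = Tree(root)

    for n in tree.postorder():
        limit = 3 if n is root else 2
        if len(n.children) > limit:
            if resolve_polytomies:
                _resolve_polytomy(n)
            else:
                raise TreeError(
                    f"multifurcation ({len(n.children)} children); "
                    "pass resolve_polytomies=True to resolve arbitrarily"
                )

    names = tree.leaf_names()
    if len(names) != len(set(names)):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise TreeError(f"duplicate leaf labels: {dup}")
    if any(name is None for name in names):
        raise TreeError("unlabeled leaf in newick input")
    return tree


def write_newick(tree: Tree, digits: int = 10) -> str:
    """Serialize to newick with branch lengths at ``digits`` significant digits."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            body = node.name
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
        if node is tree.root:
            return body
        return f"{body}:{node.length:.{digits}g}"

    return fmt(tree.root) + ";"


def unroot(tree: Tree) -> Tree:
    """Return a copy whose root is trifurcating (suppressing a rooted root).

    A bifurcating root is presentational only under unrooted semantics; the
    two root-adjacent branches are merged (lengths summed) onto one edge.
    Trees with fewer than 3 leaves are returned as plain copies.
    """
    t = tree.copy()
    root = t.root
    if len(root.children) != 2:
        return t
    a, b = root.children
    if a.is_leaf and b.is_leaf:
        return t
    inner, other = (a, b) if not a.is_leaf else (b, a)
    other.length += inner.length
    inner.length = 0.0
    root.children = inner.children + [other]
    inner.children = []
    return t


def path_length(tree: Tree, a: str, b: str) -> float:
    """Patristic distance between two leaves."""
    dists = leaf_distances_from(tree)
    try:
        return dists[a][b]
    except KeyError as exc:
        raise TreeError(f"unknown taxon: {exc}") from exc


def leaf_distances_from(tree: Tree) -> dict[str, dict[str, float]]:
    """All pairwise patristic distances among leaves."""
    # For each node, distances from that node to leaves in its subtree.
    below: dict[int, dict[str, float]] = {}
    result: dict[str, dict[str, float]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = {node.name: 0.0}
            result.setdefault(node.name, {})
            continue
        maps = [
            {k: v + c.length for k, v in below[id(c)].items()}
            for c in node.children
        ]
        for i in range(len(maps)):
            for j in range(i + 1, len(maps)):
                for na, da in maps[i].items():
                    for nb, db in maps[j].items():
                        result[na][nb] = result[nb][na] = da + db
        merged: dict[str, float] = {}
        for m in maps:
            merged.update(m)
        below[id(node)] = merged
    return result


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


class Split:
    """A bipartition of the taxon set, canonically oriented.

    The side containing the lexicographically smallest taxon is ``side_a``,
    so equality and hashing are well defined regardless of construction
    order.
    """

    __slots__ = ("side_a", "side_b")

    def __init__(self, side_a, side_b):
        a, b = frozenset(side_a), frozenset(side_b)
        if not a or not b:
            raise TreeError("split sides must be non-empty")
        if a & b:
            raise TreeError("split sides must be disjoint")
        if min(a | b) in b:
            a, b = b, a
        self.side_a, self.side_b = a, b

    @classmethod
    def from_clade(cls, taxa, all_taxa) -> "Split":
        taxa = frozenset(taxa)
        return cls(taxa, frozenset(all_taxa) - taxa)

    def __eq__(self, other):
        return (isinstance(other, Split)
                and self.side_a == other.side_a
                and self.side_b == other.side_b)

    def __hash__(self):
        return hash((self.side_a, self.side_b))

    def __repr__(self):
        fmt = lambda s: ",".join(sorted(s))
        return f"{fmt(self.side_a)} | {fmt(self.side_b)}"

    def to_tsv(self) -> str:
        return (",".join(sorted(self.side_a)) + "\t"
                + ",".join(sorted(self.side_b)))

    @classmethod
    def from_tsv(cls, line: str) -> "Split":
        a, b = line.rstrip("\n").split("\t")
        return cls(a.split(","), b.split(","))

    def compatible_with(self, other: "Split") -> bool:
        """Two splits are compatible iff some pair of sides is disjoint."""
        return any(
            not (sa & sb)
            for sa in (self.side_a, self.side_b)
            for sb in (other.side_a, other.side_b)
        )


def _leafsets(tree: Tree) -> dict[int, frozenset]:
    out: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            out[id(node)] = frozenset([node.name])
        else:
            s = frozenset()
            for c in node.children:
                s |= out[id(c)]
            out[id(node)] = s
    return out


def extract_splits(tree: Tree) -> set[Split]:
    """All nontrivial splits (one per internal branch); needs >= 4 leaves."""
    all_taxa = frozenset(tree.leaf_names())
    if len(all_taxa) < 4:
        raise TreeError("splits require at least 4 leaves")
    leafsets = _leafsets(tree)
    splits = set()
    for node in tree.postorder():
        if node is tree.root:
            continue
        side = leafsets[id(node)]
        if 2 <= len(side) <= len(all_taxa) - 2:
            splits.add(Split(side, all_taxa - side))
    return splits


def is_monophyletic(tree: Tree, taxa) -> bool:
    """Unrooted monophyly: some branch separates ``taxa`` from the rest.

    Singletons and the full leaf set are monophyletic by convention.
    """
    taxa = frozenset(taxa)
    all_taxa = frozenset(tree.leaf_names())
    unknown = taxa - all_taxa
    if unknown:
        raise TreeError(f"unknown taxa: {sorted(unknown)}")
    if len(taxa) in (1, len(all_taxa)):
        return True
    if not taxa:
        raise TreeError("empty taxon set")
    for side in _leafsets(tree).values():
        if side == taxa or side == all_taxa - taxa:
            return True
    return False


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------


@dataclass
class Alignment:
    """Taxa-by-sites matrix of amino-acid codes 0-19, with 20 = gap/unknown."""

    taxa: list[str]
    data: np.ndarray  # (n_taxa, n_sites) uint8
    site_meta: object | None = field(default=None, repr=False)

    def __post_init__(self):
        self.data = np.ascontiguousarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-D")
        if len(self.taxa) != self.data.shape[0]:
            raise AlignmentError("taxa count does not match matrix rows")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon names")
        if self.data.size and self.data.max() > GAP_CODE:
            raise AlignmentError(f"state codes must be in 0..{GAP_CODE}")

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    # -- construction ------------------------------------------------------

    @classmethod
    def from_sequences(cls, sequences: dict[str, str]) -> "Alignment":
        taxa = list(sequences)
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) > 1:
            raise AlignmentError("sequences differ in length")
        rows = [
            _ENCODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
            for s in sequences.values()
        ]
        data = (np.vstack(rows) if rows
                else np.zeros((0, 0), dtype=np.uint8))
        return cls(taxa, data)

    def sequences(self) -> dict[str, str]:
        return {t: "".join(_DECODE[row]) for t, row in zip(self.taxa, self.data)}

    # -- manipulation ------------------------------------------------------

    def take_sites(self, indices) -> "Alignment":
        return Alignment(list(self.taxa), self.data[:, np.asarray(indices)])

    def subset_taxa(self, taxa) -> "Alignment":
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in index]
        if missing:
            raise AlignmentError(f"unknown taxa: {missing}")
        rows = [index[t] for t in taxa]
        return Alignment(list(taxa), self.data[rows])

    @classmethod
    def concatenate(cls, alignments) -> "Alignment":
        alignments = list(alignments)
        if not alignments:
            raise AlignmentError("nothing to concatenate")
        taxa = alignments[0].taxa
        blocks = []
        for a in alignments:
            if a.taxa != taxa:
                a = a.subset_taxa(taxa)
            blocks.append(a.data)
        return cls(list(taxa), np.hstack(blocks))

    def state_frequencies(self) -> np.ndarray:
        """Observed frequencies of the 20 amino acids, gaps excluded."""
        counts = np.bincount(self.data.ravel(), minlength=21)[:20].astype(float)
        total = counts.sum()
        if total == 0:
            return np.full(20, 1 / 20)
        return counts / total

    # -- I/O ---------------------------------------------------------------

    def _to_biopython(self) -> MultipleSeqAlignment:
        return MultipleSeqAlignment(
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences().items()
        )

    @classmethod
    def _from_biopython(cls, msa) -> "Alignment":
        return cls.from_sequences({rec.id: str(rec.seq) for rec in msa})

    def write_fasta(self, path) -> None:
        AlignIO.write(self._to_biopython(), path, "fasta")

    @classmethod
    def read_fasta(cls, path) -> "Alignment":
        return cls._from_biopython(AlignIO.read(path, "fasta"))

    def write_phylip(self, path) -> None:
        AlignIO.write(self._to_biopython(), path, "phylip-relaxed")

    @classmethod
    def read_phylip(cls, path) -> "Alignment":
        return cls._from_biopython(AlignIO.read(path, "phylip-relaxed"))


def subsample_sites(alignment: Alignment, n: int, seed) -> Alignment:
    """Draw ``n`` distinct columns uniformly without replacement."""
    if n > alignment.n_sites:
        raise AlignmentError(
            f"cannot draw {n} sites from {alignment.n_sites}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(alignment.n_sites, size=n, replace=False)
    return alignment.take_sites(idx)


def prune_taxa(tree: Tree, alignment: Alignment | None, drop):
    """Remove taxa from a tree (and matching alignment rows).

    Degree-2 nodes created by the removal are suppressed with their adjacent
    branch lengths summed, so pairwise patristic distances among survivors
    are unchanged.  At least 4 leaves must remain.
    """
    drop = frozenset(drop)
    leaf_set = frozenset(tree.leaf_names())
    unknown = drop - leaf_set
    if unknown:
        raise TreeError(f"unknown taxa: {sorted(unknown)}")
    survivors = leaf_set - drop
    if len(survivors) < 4:
        raise TreeError("fewer than 4 taxa would remain")

    def rec(node: Node) -> Node | None:
        if node.is_leaf:
            return None if node.name in drop else Node(node.name, node.length)
        kept = [k for c in node.children if (k := rec(c)) is not None]
        if not kept:
            return None
        if len(kept) == 1:
            kept[0].length += node.length
            return kept[0]
        return Node(node.name, node.length, kept)

    root = rec(tree.root)
    if len(root.children) == 1:  # degree-1 root: promote the child
        root = root.children[0]
    root.length = 0.0
    clades = {
        name: members - drop
        for name, members in tree.clades.items()
        if members - drop
    }
    new_tree = Tree(root, clades)
    new_aln = None
    if alignment is not None:
        keep = [t for t in alignment.taxa if t not in drop]
        new_aln = alignment.subset_taxa(keep)
    return new_tree, new_aln
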