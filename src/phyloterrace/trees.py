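"""Tree I/O and topology primitives.

Trees are held as :class:`dendropy.Tree` objects, but every comparison in this
package is topological and label-based: a tree is reduced to its set of
nontrivial bipartitions (label splits), so trees parsed from different files
or built by different code paths compare correctly.  Branch lengths and
support values are parsed and ignored — terrace theory depends on topology
only.

The module covers Newick parsing/writing (canonical, deterministic output),
restriction to a label subset (induced subtrees), bipartition extraction,
the resolution index rho, strict and majority-rule consensus, and rooting at
a leaf (the gateway to the rooted-triplet machinery in :mod:`.terrace`).
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence

import dendropy

from .errors import (
    IncompatibleSplitsError,
    LeafSetMismatchError,
    NewickError,
    UnknownLabelError,
)

Tree = dendropy.Tree

__all__ = [
    "Tree",
    "Bipartition",
    "parse_newick",
    "parse_newick_list",
    "read_newick_file",
    "write_newick",
    "restrict",
    "bipartition_set",
    "resolution_rho",
    "strict_consensus",
    "majority_rule_consensus",
    "root_at",
    "leaf_labels",
    "tree_from_splits",
]


class Bipartition:
    """A split of a leaf-label set into two non-empty blocks.

    Stored canonically: the block containing the lexicographically smallest
    label comes first.  Two bipartitions are equal iff their block pairs are
    equal; hashing follows suit, so sets of bipartitions compare trees.
    """

    __slots__ = ("first", "second", "_hash")

    def __init__(self, block_a: Iterable[str], block_b: Iterable[str]):
        a = frozenset(block_a)
        b = frozenset(block_b)
        if not a or not b:
            raise ValueError("bipartition blocks must be non-empty")
        if a & b:
            raise ValueError("bipartition blocks must be disjoint")
        if min(a) > min(b):
            a, b = b, a
        self.first = a
        self.second = b
        self._hash = hash((self.first, self.second))

    @property
    def is_trivial(self) -> bool:
        """True when one block is a single leaf (present in every tree)."""
        return len(self.first) < 2 or len(self.second) < 2

    @property
    def labels(self) -> frozenset:
        return self.first | self.second

    def restricted(self, labels: frozenset) -> "Bipartition | None":
        """The bipartition induced on ``labels``; None if it degenerates."""
        a = self.first & labels
        b = self.second & labels
        if not a or not b:
            return None
        return Bipartition(a, b)

    def __eq__(self, other):
        return (
            isinstance(other, Bipartition)
            and self.first == other.first
            and self.second == other.second
        )

    def __hash__(self):
        return self._hash

    def __repr__(self):
        fmt = lambda s: ",".join(sorted(s))
        return f"{fmt(self.first)} | {fmt(self.second)}"


# ---------------------------------------------------------------------------
# parsing / writing


def parse_newick(text: str) -> Tree:
    """Parse a single Newick tree.

    Quoted labels, branch lengths and internal-node labels are accepted;
    non-topology payload is ignored downstream.  Duplicate or empty leaf
    labels and malformed parenthesization raise :class:`NewickError`.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises schema-specific subclasses
        raise NewickError(f"could not parse Newick string: {exc}") from exc
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise NewickError("empty leaf label in Newick input")
        labels.append(leaf.taxon.label)
    if len(labels) != len(set(labels)):
        dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
        raise NewickError(f"duplicate leaf labels: {', '.join(dupes)}")
    return tree


def parse_newick_list(text: str) -> list[Tree]:
    """Parse a multi-tree Newick source (one tree per line/statement)."""
    trees = []
    for line in text.splitlines():
        line = line.strip()
        if line:
            trees.append(parse_newick(line))
    return trees


def read_newick_file(path) -> list[Tree]:
    with io.open(path, "r", encoding="utf-8") as fh:
        return parse_newick_list(fh.read())


def leaf_labels(tree: Tree) -> frozenset:
    return frozenset(
        leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon
    )


def _node_clusters(tree: Tree) -> dict:
    """Map each node to the frozenset of leaf labels below it (as rooted)."""
    clusters = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            clusters[node] = frozenset([node.taxon.label]) if node.taxon else frozenset()
        else:
            acc = frozenset()
            for child in node.child_nodes():
                acc |= clusters[child]
            clusters[node] = acc
    return clusters


def bipartition_set(tree: Tree) -> frozenset:
    """All nontrivial bipartitions of the (unrooted sense) tree.

    At most n-3 elements, with equality exactly when the tree is binary.
    """
    labels = leaf_labels(tree)
    n = len(labels)
    if n < 4:
        return frozenset()
    out = set()
    clusters = _node_clusters(tree)
    for node, below in clusters.items():
        if 2 <= len(below) <= n - 2:
            out.add(Bipartition(below, labels - below))
    return frozenset(out)


def rooted_clusters(tree: Tree) -> frozenset:
    """Proper clusters (internal-node leaf sets) of a rooted tree."""
    labels = leaf_labels(tree)
    clusters = _node_clusters(tree)
    return frozenset(
        c for c in clusters.values() if 2 <= len(c) < len(labels)
    )


def resolution_rho(tree: Tree) -> float:
    """Resolution rho: nontrivial bipartitions / (n - 3).

    1.0 for a binary (unrooted) tree, 0.0 for a star.  Rooted input is
    treated as its unrooted topology.  Undefined for n < 4.
    """
    n = len(leaf_labels(tree))
    if n < 4:
        raise ValueError(f"resolution rho is undefined for n={n} (< 4 leaves)")
    return len(bipartition_set(tree)) / (n - 3)


# ---------------------------------------------------------------------------
# building trees from splits / clusters


def _containment_forest(leaves: frozenset, clusters: Iterable[frozenset]):
    """Nest a laminar family of proper clusters; return nested-tuple tree.

    The returned structure is the rooted tree whose root spans ``leaves`` and
    whose internal nodes are the given clusters.  Leaves are label strings,
    internal nodes are tuples of children, ordered by smallest descendant
    label (the package-wide canonical child order).
    """
    uniq = sorted(
        {frozenset(c) for c in clusters}, key=lambda c: (-len(c), min(c))
    )
    for c in uniq:
        if not c <= leaves:
            raise IncompatibleSplitsError("cluster exceeds the leaf universe")
    # parent[i] = index of smallest strictly-containing cluster, or None
    children: dict = {None: []}
    for i, c in enumerate(uniq):
        parent = None
        for j in range(i - 1, -1, -1):
            if c < uniq[j]:
                parent = j
                break
            if c & uniq[j] and not c < uniq[j]:
                raise IncompatibleSplitsError(
                    "clusters are not pairwise compatible (not laminar)"
                )
        children.setdefault(i, [])
        children[parent].append(i)
    # check remaining laminarity violations among disjoint-looking pairs
    for i, c in enumerate(uniq):
        for j in range(i):
            if c & uniq[j] and not c < uniq[j]:
                raise IncompatibleSplitsError(
                    "clusters are not pairwise compatible (not laminar)"
                )
    # assign each leaf to its smallest containing cluster
    leaf_home: dict = {}
    for lab in leaves:
        home = None
        for i in range(len(uniq) - 1, -1, -1):
            if lab in uniq[i]:
                home = i
                break
        leaf_home.setdefault(home, []).append(lab)

    def build(idx):
        kids = [build(k) for k in children.get(idx, [])]
        kids.extend(leaf_home.get(idx, []))
        kids.sort(key=_min_leaf)
        if idx is None:
            return tuple(kids)
        if len(kids) == 1:
            return kids[0]  # suppress degree-2 node
        return tuple(kids)

    top = build(None)
    if not isinstance(top, tuple):
        top = (top,)
    return top


def _min_leaf(nested) -> str:
    while isinstance(nested, tuple):
        nested = min(nested, key=_min_leaf)
    return nested


def nested_to_newick(nested, suffix=";") -> str:
    def ser(nd):
        if isinstance(nd, tuple):
            return "(" + ",".join(ser(c) for c in nd) + ")"
        return _quote_label(nd)

    if isinstance(nested, tuple):
        return ser(nested) + suffix
    return _quote_label(nested) + suffix


_NEEDS_QUOTE = set("()[]{}/\\,;:=*'\"`<> \t\n")


def _quote_label(label: str) -> str:
    if any(ch in _NEEDS_QUOTE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def tree_from_splits(labels: Iterable[str], splits: Iterable[Bipartition]) -> Tree:
    """Unrooted tree whose nontrivial bipartition set is exactly ``splits``."""
    leaves = frozenset(labels)
    if not leaves:
        raise ValueError("empty label set")
    if len(leaves) == 1:
        return parse_newick(next(iter(leaves)) + ";")
    anchor = min(leaves)
    clusters = []
    for s in splits:
        if s.labels != leaves:
            raise LeafSetMismatchError(
                "split labels do not match the leaf universe",
                missing=leaves - s.labels,
                extra=s.labels - leaves,
            )
        if s.is_trivial:
            continue
        clusters.append(s.second if anchor in s.first else s.first)
    nested = _containment_forest(leaves, clusters)
    tree = parse_newick(nested_to_newick(nested))
    tree.is_rooted = False
    return tree


def tree_from_clusters(leaves: Iterable[str], clusters: Iterable[frozenset]) -> Tree:
    """Rooted tree from a laminar family of proper clusters."""
    leaves = frozenset(leaves)
    if len(leaves) == 1:
        tree = parse_newick(next(iter(leaves)) + ";")
    else:
        nested = _containment_forest(leaves, clusters)
        tree = parse_newick(nested_to_newick(nested))
    tree.is_rooted = True
    return tree


def write_newick(tree: Tree) -> str:
    """Canonical Newick serialization.

    Children are ordered by their smallest descendant label, so two
    topologically identical trees serialize identically.  Unrooted trees are
    written from their bipartition set; rooted trees preserve their clusters.
    Branch lengths are dropped (terrace computations never use them).
    """
    labels = leaf_labels(tree)
    if len(labels) == 1:
        return _quote_label(next(iter(labels))) + ";"
    if tree.is_rooted:
        nested = _containment_forest(labels, rooted_clusters(tree))
    else:
        anchor = min(labels)
        clusters = [
            s.second if anchor in s.first else s.first
            for s in bipartition_set(tree)
        ]
        nested = _containment_forest(labels, clusters)
    return nested_to_newick(nested)


# ---------------------------------------------------------------------------
# restriction / rooting


def restrict(tree: Tree, labels: Iterable[str]) -> Tree:
    """The induced subtree on ``labels``: prune the rest, suppress degree-2
    nodes.  The result's splits are the input's splits restricted to
    ``labels`` (dropping any that degenerate)."""
    keep = frozenset(labels)
    have = leaf_labels(tree)
    unknown = keep - have
    if unknown:
        raise UnknownLabelError(
            f"labels not in tree: {', '.join(sorted(unknown))}"
        )
    if not keep:
        raise ValueError("cannot restrict to an empty label set")
    if tree.is_rooted:
        kept = [c & keep for c in rooted_clusters(tree)]
        return tree_from_clusters(keep, [c for c in kept if 2 <= len(c) < len(keep)])
    restricted = set()
    for s in bipartition_set(tree):
        r = s.restricted(keep)
        if r is not None and not r.is_trivial:
            restricted.add(r)
    return tree_from_splits(keep, restricted)


def restricted_splits(splits: Iterable[Bipartition], labels: frozenset) -> frozenset:
    """Restrict a split set to ``labels``, keeping nontrivial results.

    Split-level counterpart of :func:`restrict`; the shared primitive behind
    both the terrace membership test and the brute-force oracle.
    """
    out = set()
    for s in splits:
        r = s.restricted(labels)
        if r is not None and not r.is_trivial:
            out.add(r)
    return frozenset(out)


def root_at(tree: Tree, label: str) -> Tree:
    """Root an unrooted tree at a leaf's attachment point.

    Returns the rooted tree on the remaining n-1 leaves; re-attaching the
    leaf at the root (see :func:`reattach_leaf`) recovers the original
    unrooted topology.
    """
    labels = leaf_labels(tree)
    if label not in labels:
        raise UnknownLabelError(f"label not in tree: {label}")
    rest = labels - {label}
    clusters = [
        s.second if label in s.first else s.first
        for s in bipartition_set(tree)
    ]
    return tree_from_clusters(rest, [c for c in clusters if 2 <= len(c) < len(rest)])


def reattach_leaf(rooted: Tree, label: str) -> Tree:
    """Inverse of :func:`root_at`: attach ``label`` at the root and unroot."""
    labels = leaf_labels(rooted)
    if label in labels:
        raise ValueError(f"label already present: {label}")
    full = labels | {label}
    splits = [
        Bipartition(c, full - c)
        for c in rooted_clusters(rooted)
        if 2 <= len(c) <= len(full) - 2
    ]
    return tree_from_splits(full, splits)


# ---------------------------------------------------------------------------
# consensus


def _check_shared_leafset(trees: Sequence[Tree]) -> frozenset:
    if not trees:
        raise ValueError("need at least one tree")
    base = leaf_labels(trees[0])
    for t in trees[1:]:
        lab = leaf_labels(t)
        if lab != base:
            raise LeafSetMismatchError(
                "trees do not share one leaf set",
                missing=base - lab,
                extra=lab - base,
            )
    return base


def strict_consensus(trees: Sequence[Tree]) -> Tree:
    """Tree whose nontrivial splits are those shared by every input tree."""
    labels = _check_shared_leafset(trees)
    common = set(bipartition_set(trees[0]))
    for t in trees[1:]:
        common &= bipartition_set(t)
        if not common:
            break
    return tree_from_splits(labels, common)


def majority_rule_consensus(trees: Sequence[Tree], threshold: float = 0.5) -> Tree:
    """Splits occurring in strictly more than ``threshold`` of the inputs.

    The strict inequality is the standard convention: a split in exactly half
    the trees is excluded.  For threshold >= 0.5 the retained splits are
    pairwise compatible, so the tree always exists.
    """
    if threshold < 0.5:
        raise ValueError("majority-rule threshold must be >= 0.5")
    labels = _check_shared_leafset(trees)
    counts: dict = {}
    for t in trees:
        for s in bipartition_set(t):
            counts[s] = counts.get(s, 0) + 1
    cutoff = threshold * len(trees)
    keep = [s for s, c in counts.items() if c > cutoff]
    return tree_from_splits(labels, keep)


def split_support(trees: Sequence[Tree]) -> dict:
    """Fraction of input trees containing each observed split."""
    _check_shared_leafset(trees)
    counts: dict = {}
    for t in trees:
        for s in bipartition_set(t):
            counts[s] = counts.get(s, 0) + 1
    n = len(trees)
    return {s: c / n for s, c in counts.items()}
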