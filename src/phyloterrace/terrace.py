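"""The terrace engine.

Given a tree T on taxa X and a coverage matrix with taxon subsets Y_1..Y_k,
the loci induce subtrees T|Y_j.  The terrace of T is the set of all binary
unrooted trees on X that display every one of those subtrees; under
parsimony or edge-unlinked partitioned maximum likelihood all its members
score identically.

The machinery is the classic rooted-triplet route: every induced subtree is
rooted at one *comprehensive* taxon (a taxon sampled in all loci) and
decomposed into a defining set of rooted triplets a|bc.  Trees displaying
the triplets are counted, enumerated, and sampled with the
Constantinescu-Sankoff recursion over the Aho BUILD cluster graph: on a
label set L, connect b--c for every triplet a|bc inside L; the connected
components C_1..C_m are the atomic blocks, and each tree corresponds to a
choice of root bipartition of the components plus trees on the two sides.
Counts are arbitrary-precision integers (terraces reach 10^388).

The terrace strict consensus, BUILD (Adams) consensus, per-clade resolution
counts, and same-terrace test round out the surface.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

from . import trees as _t
from .coverage import CoverageMatrix, comprehensive_taxa
from .errors import (
    IncompatibleSplitsError,
    LeafSetMismatchError,
    NoComprehensiveTaxonError,
    ResolutionLimitError,
)

log = logging.getLogger(__name__)

__all__ = [
    "TripletSystem",
    "TerraceSummary",
    "induced_subtrees",
    "triplet_system",
    "count_parent_trees",
    "enumerate_parent_trees",
    "sample_parent_trees",
    "terrace_strict_consensus",
    "terrace_build_consensus",
    "clade_resolution_counts",
    "terrace_summary",
    "same_terrace",
    "format_terrace_size",
]


# A rooted triplet a|bc is stored as (a, frozenset({b, c})): b and c attach
# below a node that excludes a.
Triplet = tuple


@dataclass(frozen=True)
class TripletSystem:
    """A set of rooted triplets over a label universe."""

    universe: frozenset
    triplets: frozenset  # of (out_label, frozenset({b, c}))

    def __post_init__(self):
        for a, bc in self.triplets:
            if a in bc or len(bc) != 2 or not ({a} | bc) <= self.universe:
                raise ValueError(f"malformed triplet {a!r}|{set(bc)!r}")

    def __len__(self):
        return len(self.triplets)


@dataclass
class TerraceSummary:
    """Everything the engine reports about one tree's terrace."""

    size: int
    size_sci: str
    strict_consensus: _t.Tree
    build_consensus: _t.Tree
    clade_counts: dict  # frozenset(cluster labels) -> int
    lower_bound: bool = False

    def __post_init__(self):
        self.size_sci = format_terrace_size(self.size)


# ---------------------------------------------------------------------------
# induced subtrees and triplet decomposition


def _check_tree_matches_matrix(tree: _t.Tree, matrix: CoverageMatrix):
    tree_labels = _t.leaf_labels(tree)
    mat_labels = frozenset(matrix.taxa)
    if tree_labels != mat_labels:
        raise LeafSetMismatchError(
            "tree leaves and coverage-matrix taxa differ",
            missing=mat_labels - tree_labels,
            extra=tree_labels - mat_labels,
        )


def induced_subtrees(tree: _t.Tree, matrix: CoverageMatrix) -> list[_t.Tree]:
    """T|Y_j for each locus j (k trees, in locus order).

    Loci sampling fewer than 3 taxa yield trivially uninformative subtrees;
    they are kept here and ignored by the constraint system.
    """
    _check_tree_matches_matrix(tree, matrix)
    out = []
    for j, y in enumerate(matrix.subsets()):
        if not y:
            raise ValueError(f"locus {matrix.loci[j]!r} samples no taxa")
        out.append(_t.restrict(tree, y))
    return out


def _nested_from_tree(tree: _t.Tree, root_label: str):
    """Rooted nested-tuple form of ``tree`` rooted at ``root_label``'s
    attachment, with the root leaf removed."""
    rooted = _t.root_at(tree, root_label)
    labels = _t.leaf_labels(rooted)
    if len(labels) == 1:
        return next(iter(labels))
    return _t._containment_forest(labels, _t.rooted_clusters(rooted))


def _defining_triplets(nested, out_rep=None, acc=None) -> set:
    """Minimal defining triplet set of a binary rooted nested-tuple tree.

    For each internal node below the root, one triplet: representatives of
    its two child subtrees paired against a representative from outside the
    node.  A binary rooted tree is identified among trees on its leaf set by
    these n-2 triplets.
    """
    if acc is None:
        acc = set()
    if not isinstance(nested, tuple):
        return acc
    if len(nested) != 2:
        raise ValueError("defining triplets require a binary rooted tree")
    left, right = nested
    lrep, rrep = _t._min_leaf(left), _t._min_leaf(right)
    if out_rep is not None:
        acc.add((out_rep, frozenset((lrep, rrep))))
    _defining_triplets(left, rrep, acc)
    _defining_triplets(right, lrep, acc)
    return acc


def triplet_system(subtrees: Sequence[_t.Tree], root_label: str) -> TripletSystem:
    """Union of the defining triplets of every subtree, rooted at
    ``root_label`` (which must occur in every subtree)."""
    universe = set()
    triplets: set = set()
    for st in subtrees:
        labels = _t.leaf_labels(st)
        if root_label not in labels:
            raise NoComprehensiveTaxonError(
                f"root label {root_label!r} missing from a subtree; choose a "
                "comprehensive taxon (see coverage.comprehensive_taxa)"
            )
        universe |= labels - {root_label}
        if len(labels) < 4:
            continue  # a <=3-leaf unrooted subtree constrains nothing
        nested = _nested_from_tree(st, root_label)
        triplets |= _defining_triplets(nested)
    return TripletSystem(frozenset(universe), frozenset(triplets))


# ---------------------------------------------------------------------------
# the Constantinescu-Sankoff recursion


class _Engine:
    """Counting/enumeration/sampling over rooted trees displaying a triplet
    set, memoized by label subset."""

    def __init__(self, system: TripletSystem):
        self.universe = system.universe
        self.triplets = tuple(system.triplets)
        self._count_memo: dict = {}
        self._choice_memo: dict = {}

    # -- structure ---------------------------------------------------------

    def _components(self, labels: frozenset) -> list[frozenset]:
        """Connected components of the cluster graph on ``labels``:
        edge b--c for each triplet a|bc with a, b, c all in ``labels``."""
        parent = {x: x for x in labels}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, bc in self.triplets:
            if a in parent:
                b, c = bc
                if b in parent and c in parent:
                    rb, rc = find(b), find(c)
                    if rb != rc:
                        parent[rb] = rc
        groups: dict = {}
        for x in labels:
            groups.setdefault(find(x), set()).add(x)
        return sorted(
            (frozenset(g) for g in groups.values()), key=lambda g: min(g)
        )

    @staticmethod
    def _component_splits(comps: list[frozenset]):
        """The 2^(m-1) - 1 bipartitions of the component list into two
        non-empty groups, in a fixed canonical order."""
        m = len(comps)
        for mask in range(1, 2 ** (m - 1)):
            g1 = comps[0]
            g2 = frozenset()
            for i in range(1, m):
                if mask & (1 << (i - 1)):
                    g1 = g1 | comps[i]
                else:
                    g2 = g2 | comps[i]
            if g2:
                yield g1, g2
        # mask with all of comps[1:] joined to comps[0] leaves g2 empty and
        # is skipped; mask 0 (g1 alone) appears as its complement.
        if m >= 2:
            g1 = comps[0]
            g2 = frozenset().union(*comps[1:])
            yield g1, g2

    # -- counting ----------------------------------------------------------

    def count(self, labels: frozenset, budget: list | None = None) -> int:
        """Number of rooted binary trees on ``labels`` displaying the
        triplets.  ``budget`` (a one-element mutable list of remaining work
        units) turns a runaway count into a lower bound: exhausted
        subproblems contribute 0."""
        if len(labels) <= 2:
            return 1
        memo = self._count_memo
        if labels in memo:
            return memo[labels]
        if budget is not None:
            if budget[0] <= 0:
                return 0  # lower bound; not memoized
            budget[0] -= 1
        comps = self._components(labels)
        if len(comps) == 1:
            # cannot split at the root -> no binary tree displays the set
            # (never reached for triplets taken from a real tree)
            memo[labels] = 0
            return 0
        if len(comps) == len(labels):
            # no constraint touches this subproblem: all rooted binary
            # shapes on |L| leaves are admissible, (2|L|-3)!! of them
            total = _double_factorial(2 * len(labels) - 3)
            memo[labels] = total
            return total
        total = 0
        for g1, g2 in self._component_splits(comps):
            if budget is not None:
                budget[0] -= 1
                if budget[0] <= 0:
                    return total  # partial sum = lower bound; not memoized
            total += self.count(g1, budget) * self.count(g2, budget)
        memo[labels] = total
        return total

    # -- enumeration -------------------------------------------------------

    def enumerate(self, labels: frozenset) -> Iterator:
        """Yield each displaying rooted tree once, as a nested tuple, in the
        canonical component/split order."""
        if len(labels) == 1:
            yield next(iter(labels))
            return
        if len(labels) == 2:
            a, b = sorted(labels)
            yield (a, b)
            return
        comps = self._components(labels)
        if len(comps) == 1:
            return
        for g1, g2 in self._component_splits(comps):
            for left in self.enumerate(g1):
                for right in self.enumerate(g2):
                    if _t._min_leaf(left) <= _t._min_leaf(right):
                        yield (left, right)
                    else:
                        yield (right, left)

    # -- sampling ----------------------------------------------------------

    def sample(self, labels: frozenset, rng) -> tuple:
        """One rooted tree drawn uniformly from the displaying set."""
        if len(labels) == 1:
            return next(iter(labels))
        if len(labels) == 2:
            a, b = sorted(labels)
            return (a, b)
        if labels not in self._choice_memo:
            comps = self._components(labels)
            choices = []
            for g1, g2 in self._component_splits(comps):
                w = self.count(g1) * self.count(g2)
                if w:
                    choices.append((g1, g2, w))
            self._choice_memo[labels] = choices
        choices = self._choice_memo[labels]
        total = sum(w for _, _, w in choices)
        pick = rng.randrange(total)
        for g1, g2, w in choices:
            if pick < w:
                left = self.sample(g1, rng)
                right = self.sample(g2, rng)
                if _t._min_leaf(left) > _t._min_leaf(right):
                    left, right = right, left
                return (left, right)
            pick -= w
        raise AssertionError("unreachable")

    # -- cluster-constrained counting ---------------------------------------

    def count_with_cluster(self, cluster: frozenset) -> int:
        """Displaying trees in which ``cluster`` is a clade.

        The problem splits into the subtree on the cluster and the quotient
        where the cluster collapses to one meta-leaf; triplets straddling the
        boundary either vanish (automatically satisfied), map onto the
        meta-leaf, or are unsatisfiable (count 0).
        """
        inner = []
        quotient = []
        meta = _MetaLeaf(cluster)
        for a, bc in self.triplets:
            b, c = bc
            a_in, b_in, c_in = a in cluster, b in cluster, c in cluster
            if a_in and b_in and c_in:
                inner.append((a, bc))
            elif not a_in and b_in and c_in:
                continue  # b,c already grouped inside the clade
            elif a_in and (b_in or c_in):
                return 0  # would need a partner of `a` outside its own clade
            elif a_in:
                quotient.append((meta, bc))
            elif b_in or c_in:
                outer = c if b_in else b
                quotient.append((a, frozenset((meta, outer))))
            else:
                quotient.append((a, bc))
        inner_count = _Engine(
            TripletSystem(cluster, frozenset(inner))
        ).count(cluster)
        outer_labels = (self.universe - cluster) | {meta}
        outer_count = _Engine(
            TripletSystem(frozenset(outer_labels), frozenset(quotient))
        ).count(frozenset(outer_labels))
        return inner_count * outer_count

    def local_count(self, blocks: Sequence[frozenset]) -> int:
        """Number of ways to arrange the given child blocks below one node:
        displaying trees on the block meta-leaves under quotient triplets."""
        meta = {b: _MetaLeaf(b) for b in blocks}

        def home(x):
            for b in blocks:
                if x in b:
                    return meta[b]
            return None

        quotient = set()
        for a, bc in self.triplets:
            b, c = bc
            ha, hb, hc = home(a), home(b), home(c)
            if hb is None or hc is None or hb == hc:
                continue  # handled above or below this node
            if ha is None or ha in (hb, hc):
                continue
            quotient.add((ha, frozenset((hb, hc))))
        labels = frozenset(meta.values())
        return _Engine(TripletSystem(labels, frozenset(quotient))).count(labels)


class _MetaLeaf:
    """Stand-in label for a collapsed cluster; orders after real labels."""

    __slots__ = ("key",)

    def __init__(self, cluster: frozenset):
        self.key = tuple(sorted(cluster))

    def __eq__(self, other):
        return isinstance(other, _MetaLeaf) and self.key == other.key

    def __hash__(self):
        return hash(self.key)

    def __lt__(self, other):
        if isinstance(other, _MetaLeaf):
            return self.key < other.key
        return False  # real (str) labels sort first

    def __gt__(self, other):
        return not isinstance(other, _MetaLeaf) or other.key < self.key

    def __le__(self, other):
        return not self.__gt__(other)

    def __ge__(self, other):
        return not self.__lt__(other)

    def __repr__(self):
        return f"<{'+'.join(self.key)}>"


# ---------------------------------------------------------------------------
# public terrace operations


def _pick_root(matrix: CoverageMatrix) -> str:
    comp = comprehensive_taxa(matrix)
    if not comp:
        raise NoComprehensiveTaxonError(
            "no taxon is sampled in every locus; the rooted-triplet "
            "machinery needs a comprehensive taxon and this instance is "
            "refused rather than guessed at"
        )
    return comp[0]


def _is_binary_unrooted(tree: _t.Tree) -> bool:
    labels = _t.leaf_labels(tree)
    n = len(labels)
    if n < 4:
        return True
    return len(_t.bipartition_set(tree)) == n - 3


def _engine_for(tree: _t.Tree, matrix: CoverageMatrix):
    """Root, decompose, and wrap an engine; returns (engine, root_label)."""
    _check_tree_matches_matrix(tree, matrix)
    root = _pick_root(matrix)
    subtrees = []
    for j, y in enumerate(matrix.subsets()):
        if len(y) < 4:
            continue  # constrains nothing
        subtrees.append(_t.restrict(tree, y))
    system = triplet_system(subtrees, root) if subtrees else TripletSystem(
        frozenset(_t.leaf_labels(tree)) - {root}, frozenset()
    )
    # loci with < 4 taxa leave their labels out of the subtree union; the
    # universe must still be all taxa minus the root
    universe = frozenset(_t.leaf_labels(tree)) - {root}
    system = TripletSystem(universe, system.triplets)
    return _Engine(system), root


def _nested_to_unrooted(nested, root_label: str) -> _t.Tree:
    if isinstance(nested, tuple):
        newick = _t.nested_to_newick(tuple(nested) + (root_label,))
    else:
        newick = _t.nested_to_newick((nested, root_label))
    tree = _t.parse_newick(newick)
    tree.is_rooted = False
    return tree


def count_parent_trees(
    tree: _t.Tree,
    matrix: CoverageMatrix,
    work_cap: int | None = None,
    resolution_cap: int = 10_000,
) -> tuple[int, bool]:
    """Terrace size: binary unrooted trees on X displaying every induced
    subtree.  Returns ``(count, is_lower_bound)``.

    Polytomies in the input tree are soft: the result is the sum of terrace
    sizes over all binary resolutions (refused above ``resolution_cap``
    combined resolutions).  ``work_cap`` bounds recursion expansions; an
    exhausted budget yields a flagged lower bound.
    """
    _check_tree_matches_matrix(tree, matrix)
    if _is_binary_unrooted(tree):
        engine, root = _engine_for(tree, matrix)
        budget = [work_cap] if work_cap is not None else None
        size = engine.count(engine.universe, budget)
        capped = budget is not None and budget[0] <= 0
        return size, capped
    total = 0
    capped = False
    for resolved in _binary_resolutions(tree, resolution_cap):
        sub, c = count_parent_trees(resolved, matrix, work_cap=work_cap)
        total += sub
        capped = capped or c
    return total, capped


def _binary_resolutions(tree: _t.Tree, cap: int):
    """All binary trees refining a multifurcating tree (soft polytomies)."""
    labels = sorted(_t.leaf_labels(tree))
    anchor = labels[0]
    nested = _nested_from_tree(tree, anchor)

    expected = 1
    def _count_shapes(nd):
        nonlocal expected
        if not isinstance(nd, tuple):
            return
        c = len(nd)
        if c > 2:
            expected *= _double_factorial(2 * c - 3)
        for child in nd:
            _count_shapes(child)
    _count_shapes(nested)
    if expected > cap:
        raise ResolutionLimitError(
            f"{expected} binary resolutions of input polytomies exceed the "
            f"cap of {cap}"
        )

    def _resolve(nd):
        if not isinstance(nd, tuple):
            yield nd
            return
        child_options = [list(_resolve(c)) for c in nd]
        for combo in itertools.product(*child_options):
            yield from _rooted_shapes(list(combo))

    for resolved in _resolve(nested):
        yield _nested_to_unrooted(resolved, anchor)


def _rooted_shapes(items: list):
    """All rooted binary shapes over the given subtree items."""
    if len(items) == 1:
        yield items[0]
        return
    if len(items) == 2:
        yield (items[0], items[1])
        return
    first, rest = items[0], items[1:]
    for shape in _rooted_shapes(rest):
        yield from _insert_everywhere(first, shape)


def _insert_everywhere(item, shape):
    yield (item, shape)
    if isinstance(shape, tuple) and len(shape) == 2:
        a, b = shape
        for ins in _insert_everywhere(item, a):
            yield (ins, b)
        for ins in _insert_everywhere(item, b):
            yield (a, ins)


def _double_factorial(x: int) -> int:
    out = 1
    while x > 1:
        out *= x
        x -= 2
    return out


def enumerate_parent_trees(
    tree: _t.Tree, matrix: CoverageMatrix, cap: int | None = None
) -> tuple[list[_t.Tree], bool]:
    """Materialize the terrace (distinct trees, canonical order).

    Returns ``(trees, exhausted)``; ``exhausted`` is False when ``cap``
    stopped the walk early.  Enumeration streams without memoization, so run
    time scales with the number of trees yielded.
    """
    engine, root = _engine_for(tree, matrix)
    out = []
    exhausted = True
    for nested in engine.enumerate(engine.universe):
        if cap is not None and len(out) >= cap:
            exhausted = False
            break
        out.append(_nested_to_unrooted(nested, root))
    return out, exhausted


def sample_parent_trees(
    tree: _t.Tree, matrix: CoverageMatrix, count: int, seed: int | None = None
) -> list[_t.Tree]:
    """``count`` uniform draws from the terrace (seeded, reproducible).

    At each recursion node a component bipartition is chosen with
    probability proportional to the product of its two subtree counts.
    """
    import random

    engine, root = _engine_for(tree, matrix)
    rng = random.Random(seed)
    return [
        _nested_to_unrooted(engine.sample(engine.universe, rng), root)
        for _ in range(count)
    ]


def terrace_strict_consensus(tree: _t.Tree, matrix: CoverageMatrix) -> _t.Tree:
    """Tree whose nontrivial splits occur in *every* tree on the terrace.

    Candidate splits are the input tree's own (the input is a terrace
    member, so the consensus can only lose splits); each is kept iff the
    count of terrace trees forced to contain it equals the terrace size.
    """
    engine, root = _engine_for(tree, matrix)
    size = engine.count(engine.universe)
    labels = _t.leaf_labels(tree)
    kept = []
    for split in _t.bipartition_set(tree):
        cluster = split.second if root in split.first else split.first
        if engine.count_with_cluster(cluster) == size:
            kept.append(split)
    return _t.tree_from_splits(labels, kept)


def terrace_build_consensus(tree: _t.Tree, matrix: CoverageMatrix) -> _t.Tree:
    """The BUILD (Adams) consensus of the terrace: the recursive
    cluster-graph tree of the triplet system.  Displays every triplet and is
    at least as resolved as the strict consensus."""
    engine, root = _engine_for(tree, matrix)

    def build(labels: frozenset) -> frozenset:
        """Collect the proper clusters of the BUILD tree."""
        if len(labels) <= 2:
            return frozenset()
        comps = engine._components(labels)
        if len(comps) == 1:
            raise IncompatibleSplitsError(
                "triplet system is incompatible (unexpected for triplets "
                "taken from a single tree)"
            )
        clusters = set()
        for comp in comps:
            if len(comp) >= 2:
                clusters.add(comp)
            clusters |= build(comp)
        return frozenset(clusters)

    all_labels = _t.leaf_labels(tree)
    clusters = build(engine.universe)
    splits = [
        _t.Bipartition(c, all_labels - c)
        for c in clusters
        if len(c) <= len(all_labels) - 2
    ]
    return _t.tree_from_splits(all_labels, splits)


def clade_resolution_counts(tree: _t.Tree, matrix: CoverageMatrix) -> dict:
    """Per-clade ambiguity: for each internal node of the terrace strict
    consensus (keyed by its cluster, rooted at the comprehensive taxon), the
    number of distinct local resolutions across the terrace.  The product of
    the counts is the terrace size."""
    engine, root = _engine_for(tree, matrix)
    sc = terrace_strict_consensus(tree, matrix)
    sc_rooted = _t.root_at(sc, root)
    clusters = sorted(
        _t.rooted_clusters(sc_rooted), key=lambda c: (-len(c), min(c))
    )
    top = frozenset(_t.leaf_labels(sc_rooted))
    counts: dict = {}
    for node_cluster in [top] + clusters:
        children: list = []
        covered: set = set()
        for c in clusters:
            if c < node_cluster and not any(c < other for other in children):
                children.append(c)
                covered |= c
        children.extend(
            frozenset([x]) for x in node_cluster - covered
        )
        counts[node_cluster] = engine.local_count(children)
    return counts


def same_terrace(t1: _t.Tree, t2: _t.Tree, matrix: CoverageMatrix) -> bool:
    """True iff t1 and t2 induce identical subtrees at every locus —
    i.e. the coverage pattern cannot tell them apart."""
    _check_tree_matches_matrix(t1, matrix)
    _check_tree_matches_matrix(t2, matrix)
    s1 = _t.bipartition_set(t1)
    s2 = _t.bipartition_set(t2)
    for y in matrix.subsets():
        if _t.restricted_splits(s1, frozenset(y)) != _t.restricted_splits(
            s2, frozenset(y)
        ):
            return False
    return True


def terrace_summary(
    tree: _t.Tree, matrix: CoverageMatrix, work_cap: int | None = None
) -> TerraceSummary:
    size, capped = count_parent_trees(tree, matrix, work_cap=work_cap)
    sc = terrace_strict_consensus(tree, matrix)
    bc = terrace_build_consensus(tree, matrix)
    counts = clade_resolution_counts(tree, matrix)
    return TerraceSummary(
        size=size,
        size_sci=format_terrace_size(size),
        strict_consensus=sc,
        build_consensus=bc,
        clade_counts=counts,
        lower_bound=capped,
    )


def format_terrace_size(size: int) -> str:
    """Exact decimal (with thousands separators) below 10^6, otherwise
    normalized scientific notation with two decimals, e.g. ``1.30E+388``."""
    if size < 0:
        raise ValueError("terrace size cannot be negative")
    if size < 1_000_000:
        return f"{size:,d}"
    digits = str(size)
    exponent = len(digits) - 1
    lead = int(digits[:4].ljust(4, "0"))
    mantissa = round(lead / 1000, 2)
    if mantissa >= 10:
        mantissa /= 10
        exponent += 1
    return f"{mantissa:.2f}E+{exponent}"
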