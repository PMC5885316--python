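"""Synthetic instances and brute-force oracles.

Random trees and random coverage matrices make every terrace operation
testable without external data, and the exhaustive oracle — enumerate all
(2n-5)!! unrooted binary topologies, keep those displaying every induced
subtree — is the definitional check the engine is validated against.

The coverage generator emulates the uniform random taxon-sampling regime
the k_min theory assumes: each taxon-locus cell is present independently
with probability d.  Real matrices are anything but uniform (phylogenetic
clustering of missingness, locus popularity); see the methods note.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import trees as _t
from .coverage import CoverageMatrix

__all__ = [
    "SyntheticSpec",
    "random_binary_tree",
    "random_coverage_matrix",
    "enumerate_all_unrooted_trees",
    "oracle_terrace",
]

_ORACLE_MAX_N = 8


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters for a random coverage matrix."""

    n: int
    k: int
    density: float
    seed: int | None = None
    ensure_comprehensive: bool = True

    def __post_init__(self):
        if self.n < 3 or self.k < 1:
            raise ValueError("need n >= 3 taxa and k >= 1 loci")
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")


def _default_labels(n: int) -> list[str]:
    return [f"t{i+1}" for i in range(n)]


# ---------------------------------------------------------------------------
# random and exhaustive topologies
#
# An unrooted binary tree on labels l0..l_{m-1} corresponds bijectively to a
# rooted binary tree on l1..l_{m-1} (the root marks l0's attachment).  Both
# the sampler and the enumerator work in that rooted nested-tuple form and
# convert at the end.


def _insert_above(node, label, counter: list):
    """Attach ``label`` above the node at preorder index ``counter[0]``."""
    if counter[0] == 0:
        counter[0] = -1
        return (label, node)
    counter[0] -= 1
    if not isinstance(node, tuple):
        return node
    a, b = node
    return (_insert_above(a, label, counter), _insert_above(b, label, counter))


def _num_nodes(nested) -> int:
    if not isinstance(nested, tuple):
        return 1
    return 1 + sum(_num_nodes(c) for c in nested)


def _rooted_to_unrooted(nested, viewpoint: str) -> _t.Tree:
    if isinstance(nested, tuple):
        newick = _t.nested_to_newick(tuple(nested) + (viewpoint,))
    else:
        newick = _t.nested_to_newick((nested, viewpoint))
    tree = _t.parse_newick(newick)
    tree.is_rooted = False
    return tree


def random_binary_tree(labels: Sequence[str], seed: int | None = None) -> _t.Tree:
    """Uniformly random unrooted binary topology on ``labels``.

    Sequential random edge attachment: each new leaf subdivides an edge
    chosen uniformly, giving each of the (2n-5)!! topologies the same
    probability.  Seeded and reproducible.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    if len(set(labels)) != len(labels):
        raise ValueError("labels must be unique")
    rng = random.Random(seed)
    nested = (labels[1], labels[2])
    for lab in labels[3:]:
        # edges of the current unrooted tree == nodes of the rooted form
        counter = [rng.randrange(_num_nodes(nested))]
        nested = _insert_above(nested, lab, counter)
    return _rooted_to_unrooted(nested, labels[0])


def _all_rooted(leaves: Sequence[str]):
    """All rooted binary nested-tuple trees on ``leaves`` (each once)."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for shape in _all_rooted(rest):
        total = _num_nodes(shape)
        for pos in range(total):
            yield _insert_above(shape, first, [pos])


def enumerate_all_unrooted_trees(labels: Sequence[str]) -> list[_t.Tree]:
    """All (2n-5)!! distinct unrooted binary topologies, each exactly once.

    Refused above n = 8 (10,395 topologies) — this is oracle substrate, not
    a production enumerator.
    """
    labels = list(labels)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 labels")
    if n > _ORACLE_MAX_N:
        raise ValueError(
            f"exhaustive enumeration refused for n={n} > {_ORACLE_MAX_N}"
        )
    return [
        _rooted_to_unrooted(nested, labels[0])
        for nested in _all_rooted(labels[1:])
    ]


# ---------------------------------------------------------------------------
# random coverage


def random_coverage_matrix(spec: SyntheticSpec) -> CoverageMatrix:
    """Bernoulli(d) coverage matrix, repaired to have no empty row or
    column, optionally with a forced comprehensive taxon.

    Repair flips the single cheapest cell per empty row/column, so achieved
    density stays within matrix granularity of the target.
    """
    rng = np.random.default_rng(spec.seed)
    presence = rng.random((spec.n, spec.k)) < spec.density
    if spec.ensure_comprehensive:
        presence[0, :] = True
    # repair: no empty rows/columns (deterministic under the seed)
    for i in range(spec.n):
        if not presence[i].any():
            presence[i, int(rng.integers(spec.k))] = True
    for j in range(spec.k):
        if not presence[:, j].any():
            presence[int(rng.integers(spec.n)), j] = True
    taxa = _default_labels(spec.n)
    loci = [f"L{j+1}" for j in range(spec.k)]
    return CoverageMatrix(tuple(taxa), tuple(loci), presence)


# ---------------------------------------------------------------------------
# the oracle


def oracle_terrace(tree: _t.Tree, matrix: CoverageMatrix):
    """Definitional terrace: filter *all* unrooted binary topologies by
    "displays every induced subtree".

    Returns ``(size, split_intersection, member_trees)``.  The display test
    is restriction plus bipartition-set equality — the same primitive as
    :func:`phyloterrace.terrace.same_terrace` — so the oracle shares no
    counting logic with the engine it validates.  Refused above n = 8.
    """
    labels = sorted(_t.leaf_labels(tree))
    if set(labels) != set(matrix.taxa):
        raise ValueError("tree leaves and matrix taxa differ")
    if len(labels) > _ORACLE_MAX_N:
        raise ValueError(f"oracle refused for n={len(labels)} > {_ORACLE_MAX_N}")
    subsets = [frozenset(y) for y in matrix.subsets()]
    target = _t.bipartition_set(tree)
    per_locus = [_t.restricted_splits(target, y) for y in subsets]
    members = []
    for cand in enumerate_all_unrooted_trees(labels):
        splits = _t.bipartition_set(cand)
        if all(
            _t.restricted_splits(splits, y) == ref
            for y, ref in zip(subsets, per_locus)
        ):
            members.append(cand)
    inter = set(_t.bipartition_set(members[0])) if members else set()
    for memb in members[1:]:
        inter &= _t.bipartition_set(memb)
    return len(members), frozenset(inter), members
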