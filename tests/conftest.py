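import numpy as np
import pytest

from phyloterrace import CoverageMatrix, parse_newick


@pytest.fixture
def five_leaf_instance():
    """The worked size-3 terrace: T = ((a,b),c,(d,e)) with loci sampling
    {a,b,c,d} and {a,b,c,e}.  The three parent trees place each of c, d, e
    as the cherry partner; only the split ab|cde survives in all of them."""
    tree = parse_newick("((a,b),c,(d,e));")
    matrix = CoverageMatrix(
        ("a", "b", "c", "d", "e"),
        ("L1", "L2"),
        np.array([[1, 1], [1, 1], [1, 1], [1, 0], [0, 1]], dtype=bool),
    )
    return tree, matrix


@pytest.fixture
def full_coverage_matrix():
    return CoverageMatrix(
        ("a", "b", "c", "d", "e"),
        ("L1", "L2"),
        np.ones((5, 2), dtype=bool),
    )


def splits_of(tree):
    from phyloterrace import bipartition_set

    return frozenset(bipartition_set(tree))
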