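"""The terrace engine: counting, enumeration, sampling, consensus, clades."""

import math

import numpy as np
import pytest

from phyloterrace import (
    CoverageMatrix,
    bipartition_set,
    clade_resolution_counts,
    count_parent_trees,
    enumerate_parent_trees,
    format_terrace_size,
    induced_subtrees,
    parse_newick,
    resolution_rho,
    same_terrace,
    sample_parent_trees,
    terrace_build_consensus,
    terrace_strict_consensus,
    terrace_summary,
    triplet_system,
)
from phyloterrace.errors import (
    LeafSetMismatchError,
    NoComprehensiveTaxonError,
    ResolutionLimitError,
)
from phyloterrace.trees import Bipartition, leaf_labels, restrict


def splits(t):
    return frozenset(bipartition_set(t))


class TestInducedSubtrees:
    def test_full_coverage_copies(self, five_leaf_instance, full_coverage_matrix):
        tree, _ = five_leaf_instance
        subs = induced_subtrees(tree, full_coverage_matrix)
        assert len(subs) == 2
        assert all(splits(s) == splits(tree) for s in subs)

    def test_restriction_per_locus(self, five_leaf_instance):
        tree, matrix = five_leaf_instance
        subs = induced_subtrees(tree, matrix)
        assert splits(subs[0]) == {Bipartition("ab", "cd")}
        assert leaf_labels(subs[1]) == {"a", "b", "c", "e"}

    def test_taxon_mismatch(self, five_leaf_instance):
        _, matrix = five_leaf_instance
        with pytest.raises(LeafSetMismatchError):
            induced_subtrees(parse_newick("((a,b),(c,f));"), matrix)


class TestTripletSystem:
    def test_manual_decomposition(self):
        sub = parse_newick("((a,b),c,d);")
        system = triplet_system([sub], "c")
        assert ("d", frozenset("ab")) in system.triplets

    def test_cherry_contributes_nothing(self):
        system = triplet_system([parse_newick("(a,b,c);")], "c")
        assert len(system) == 0

    def test_union_over_subtrees(self):
        s1 = parse_newick("((a,b),c,d);")
        s2 = parse_newick("((a,b),c,e);")
        system = triplet_system([s1, s2], "c")
        assert {("d", frozenset("ab")), ("e", frozenset("ab"))} <= system.triplets

    def test_missing_root_is_an_error(self):
        with pytest.raises(NoComprehensiveTaxonError, match="comprehensive"):
            triplet_system([parse_newick("((a,b),c,d);")], "z")


class TestCounting:
    def test_worked_example_size_three(self, five_leaf_instance):
        tree, matrix = five_leaf_instance
        size, lower = count_parent_trees(tree, matrix)
        assert size == 3 and not lower

    def test_full_coverage_size_one(self, five_leaf_instance, full_coverage_matrix):
        tree, _ = five_leaf_instance
        assert count_parent_trees(tree, full_coverage_matrix) == (1, False)

    def test_one_full_locus_suffices(self, five_leaf_instance):
        tree, _ = five_leaf_instance
        matrix = CoverageMatrix(
            ("a", "b", "c", "d", "e"),
            ("full", "sparse"),
            np.array([[1, 1], [1, 0], [1, 1], [1, 0], [1, 1]], bool),
        )
        assert count_parent_trees(tree, matrix)[0] == 1

    def test_no_comprehensive_taxon_refused(self):
        tree = parse_newick("((a,b),(c,d));")
        matrix = CoverageMatrix(
            ("a", "b", "c", "d"),
            ("L1", "L2"),
            np.array([[1, 0], [0, 1], [1, 0], [0, 1]], bool),
        )
        with pytest.raises(NoComprehensiveTaxonError):
            count_parent_trees(tree, matrix)

    def test_unconstraining_locus_leaves_all_of_tree_space(self):
        # a 3-taxon locus constrains nothing: the terrace is all of the
        # (2*9-5)!! = 135,135 trees on 9 leaves
        labels = tuple("abcdefghi")
        tree = parse_newick("(((a,b),(c,d)),((e,f),(g,h)),i);")
        presence = np.zeros((9, 1), bool)
        presence[:3] = True  # a, b, c only
        matrix = CoverageMatrix(labels, ("L1",), presence)
        assert count_parent_trees(tree, matrix)[0] == 135135

    def test_work_cap_gives_flagged_lower_bound(self):
        # 12 taxa, one locus sampling {a,b,c,d}: a single rooted triplet
        # survives, so exactly one third of the 19!! rooted trees on 11
        # leaves display it — big enough that a tiny work budget cannot
        # finish, and the capped result must be a flagged undercount
        labels = tuple("abcdefghijkl")
        tree = parse_newick(
            "(((a,b),(c,d)),((e,f),(g,h)),((i,j),(k,l)));"
        )
        presence = np.zeros((12, 1), bool)
        presence[:4] = True
        matrix = CoverageMatrix(labels, ("L1",), presence)
        full_size, lower = count_parent_trees(tree, matrix)
        double_fact_19 = math.prod(range(19, 1, -2))
        assert not lower and full_size == double_fact_19 // 3
        capped_size, capped = count_parent_trees(tree, matrix, work_cap=10)
        assert capped and capped_size < full_size


class TestPolytomies:
    def test_soft_polytomy_sums_resolutions(self, full_coverage_matrix):
        # unresolved (c,d,e) under full coverage: each binary resolution is
        # its own size-1 terrace, so the soft-polytomy count is 3
        tree = parse_newick("((a,b),c,d,e);")
        size, _ = count_parent_trees(tree, full_coverage_matrix)
        assert size == 3

    def test_resolution_cap_refuses(self, full_coverage_matrix):
        tree = parse_newick("(a,b,c,d,e);")
        with pytest.raises(ResolutionLimitError):
            count_parent_trees(tree, full_coverage_matrix, resolution_cap=2)


class TestEnumeration:
    def test_worked_example_members(self, five_leaf_instance):
        tree, matrix = five_leaf_instance
        members, exhausted = enumerate_parent_trees(tree, matrix)
        assert exhausted
        expected = {
            splits(parse_newick("((a,b),c,(d,e));")),
            splits(parse_newick("((a,b),d,(c,e));")),
            splits(parse_newick("((a,b),e,(c,d));")),
        }
        assert {splits(m) for m in members} == expected

    def test_full_coverage_enumerates_input(self, five_leaf_instance, full_coverage_matrix):
        tree, _ = five_leaf_instance
        members, _ = enumerate_parent_trees(tree, full_coverage_matrix)
        assert len(members) == 1 and splits(members[0]) == splits(tree)

    def test_cap_contract(self, five_leaf_instance):
        tree, matrix = five_leaf_instance
        members, exhausted = enumerate_parent_trees(tree, matrix, cap=2)
        assert len(members) == 2 and not exhausted

    def test_members_share_the_terrace(self, five_leaf_instance):
        tree, matrix = five_leaf_instance
        members, _ = enumerate_parent_trees(tree, matrix)
        assert all(same_terrace(tree, m, matrix) for m in members)


class TestSampling:
    def test_size_one_always_input(self, five_leaf_instance, full_coverage_matrix):
        tree, _ = five_leaf_instance
        for s in sample_parent_trees(tree, full_coverage_matrix, 5, seed=1):
            assert splits(s) == splits(tree)

    def test_seed_reproducibility(self, five_leaf_instance):
        tree, matrix = five_leaf_instance
        a = sample_parent_trees(tree, matrix, 20, seed=42)
        b = sample_parent_trees(tree, matrix, 20, seed=42)
        assert [splits(x) for x in a] == [splits(x) for x in b]

    def test_uniformity_chi_square(self, five_leaf_instance):
        from scipy.stats import chisquare

        tree, matrix = five_leaf_instance
        draws = sample_parent_trees(tree, matrix, 30_000, seed=7)
        counts: dict = {}
        for d in draws:
            counts[splits(d)] = counts.get(splits(d), 0) + 1
        assert len(counts) == 3
        _, p = chisquare(list(counts.values()))
        assert p > 0.001


class TestConsensusAndClades:
    def test_strict_consensus_single_split(self, five_leaf_instance):
        tree, matrix = five_leaf_instance
        sc = terrace_strict_consensus(tree, matrix)
        assert splits(sc) == {Bipartition("ab", "cde")}
        assert resolution_rho(sc) == 0.5

    def test_size_one_terrace_returns_input(self, five_leaf_instance, full_coverage_matrix):
        tree, _ = five_leaf_instance
        sc = terrace_strict_consensus(tree, full_coverage_matrix)
        assert splits(sc) == splits(tree)
        assert resolution_rho(sc) == 1.0

    def test_build_consensus_worked_example(self, five_leaf_instance):
        tree, matrix = five_leaf_instance
        bc = terrace_build_consensus(tree, matrix)
        # cherry ab retained; c, d, e unresolved
        assert splits(bc) == {Bipartition("ab", "cde")}

    def test_build_at_least_as_resolved_as_strict(self, five_leaf_instance):
        tree, matrix = five_leaf_instance
        sc = terrace_strict_consensus(tree, matrix)
        bc = terrace_build_consensus(tree, matrix)
        assert splits(sc) <= splits(bc)

    def test_clade_counts_product(self, five_leaf_instance):
        tree, matrix = five_leaf_instance
        counts = clade_resolution_counts(tree, matrix)
        assert sorted(counts.values()) == [1, 3]
        assert math.prod(counts.values()) == 3

    def test_size_one_all_counts_one(self, five_leaf_instance, full_coverage_matrix):
        tree, _ = five_leaf_instance
        counts = clade_resolution_counts(tree, full_coverage_matrix)
        assert set(counts.values()) == {1}

    def test_summary_bundles_everything(self, five_leaf_instance):
        tree, matrix = five_leaf_instance
        s = terrace_summary(tree, matrix)
        assert s.size == 3 and s.size_sci == "3" and not s.lower_bound
        assert math.prod(s.clade_counts.values()) == s.size


class TestSameTerrace:
    def test_reflexive(self, five_leaf_instance):
        tree, matrix = five_leaf_instance
        assert same_terrace(tree, tree, matrix)

    def test_two_members_of_worked_terrace(self, five_leaf_instance):
        tree, matrix = five_leaf_instance
        other = parse_newick("((a,b),d,(c,e));")
        assert same_terrace(tree, other, matrix)

    def test_distinguishable_trees(self):
        matrix = CoverageMatrix(
            ("a", "b", "c", "d", "e"),
            ("L1",),
            np.array([[1], [1], [1], [1], [0]], bool),
        )
        t1 = parse_newick("((a,b),c,(d,e));")
        t2 = parse_newick("((a,c),b,(d,e));")
        assert not same_terrace(t1, t2, matrix)


class TestFormatting:
    @pytest.mark.parametrize(
        "size,expected",
        [
            (3, "3"),
            (973_215, "973,215"),
            (10**388 * 13 // 10, "1.30E+388"),
            (999_999, "999,999"),
        ],
    )
    def test_rendering(self, size, expected):
        assert format_terrace_size(size) == expected

    def test_huge_counts_no_overflow(self):
        n = 123456 * 10**200
        assert format_terrace_size(n) == "1.23E+205"
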