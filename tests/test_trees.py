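"""Newick I/O, restriction, bipartitions, rho, consensus, rooting."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phyloterrace import (
    Bipartition,
    bipartition_set,
    majority_rule_consensus,
    parse_newick,
    resolution_rho,
    restrict,
    root_at,
    strict_consensus,
    write_newick,
)
from phyloterrace.errors import LeafSetMismatchError, NewickError, UnknownLabelError
from phyloterrace.synthetic import random_binary_tree
from phyloterrace.trees import leaf_labels, reattach_leaf, split_support


def bip(a, b):
    return Bipartition(set(a), set(b))


class TestParse:
    def test_five_leaf_splits(self):
        t = parse_newick("((a,b),c,(d,e));")
        assert bipartition_set(t) == {bip("ab", "cde"), bip("de", "abc")}

    def test_four_leaf_single_split(self):
        t = parse_newick("((a,b),(c,d));")
        assert bipartition_set(t) == {bip("ab", "cd")}

    @pytest.mark.parametrize(
        "bad", ["((a,a),b);", "((a,b),c", "((,b),c);", "(a,b))c;("]
    )
    def test_malformed_input_rejected(self, bad):
        with pytest.raises(NewickError):
            parse_newick(bad)

    def test_duplicate_error_names_label(self):
        with pytest.raises(NewickError, match="a"):
            parse_newick("((a,a),b);")

    def test_payload_ignored(self):
        t = parse_newick("((a:0.1,b:0.2)95:0.3,c:0.1,(d:1,'e e':2):3);")
        assert leaf_labels(t) == {"a", "b", "c", "d", "e e"}
        assert bipartition_set(t) == {
            bip("ab", {"c", "d", "e e"}),
            bip({"d", "e e"}, {"a", "b", "c"}),
        }


class TestWrite:
    def test_child_order_canonicalized(self):
        t1 = parse_newick("((a,b),c,(d,e));")
        t2 = parse_newick("((e,d),(b,a),c);")
        assert write_newick(t1) == write_newick(t2)

    def test_roundtrip_preserves_splits(self):
        t = parse_newick("(((a,b),(c,d)),e,(f,g));")
        again = parse_newick(write_newick(t))
        assert bipartition_set(again) == bipartition_set(t)

    def test_single_leaf(self):
        assert write_newick(parse_newick("a;")) == "a;"

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(4, 30))
    def test_roundtrip_random_topologies(self, seed, n):
        t = random_binary_tree([f"t{i}" for i in range(n)], seed=seed)
        assert bipartition_set(parse_newick(write_newick(t))) == bipartition_set(t)


class TestRestrict:
    def test_manual_pruning(self):
        t = parse_newick("((a,b),c,(d,e));")
        r = restrict(t, {"a", "b", "c", "d"})
        assert bipartition_set(r) == {bip("ab", "cd")}

    def test_full_leafset_is_identity(self):
        t = parse_newick("((a,b),c,(d,e));")
        assert bipartition_set(restrict(t, "abcde")) == bipartition_set(t)

    def test_two_labels(self):
        t = parse_newick("((a,b),c,(d,e));")
        assert leaf_labels(restrict(t, {"a", "d"})) == {"a", "d"}

    def test_unknown_labels_listed(self):
        t = parse_newick("((a,b),c,(d,e));")
        with pytest.raises(UnknownLabelError, match="x"):
            restrict(t, {"a", "x"})

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_restriction_composes(self, seed):
        labels = [f"t{i}" for i in range(9)]
        t = random_binary_tree(labels, seed=seed)
        big = set(labels[:7])
        small = set(labels[:5])
        once = restrict(t, small)
        twice = restrict(restrict(t, big), small)
        assert bipartition_set(once) == bipartition_set(twice)


class TestBipartitionsAndRho:
    def test_star_tree_has_no_splits(self):
        t = parse_newick("(a,b,c,d,e);")
        assert bipartition_set(t) == frozenset()
        assert resolution_rho(t) == 0.0

    def test_caterpillar_has_n_minus_3(self):
        t = parse_newick("(a,(b,(c,(d,(e,f)))));")
        assert len(bipartition_set(t)) == 3
        assert resolution_rho(t) == 1.0

    def test_partial_resolution(self):
        t = parse_newick("((a,b),c,d,e);")
        assert resolution_rho(t) == 0.5

    def test_undefined_below_four(self):
        with pytest.raises(ValueError):
            resolution_rho(parse_newick("(a,b,c);"))

    def test_canonical_block_order_and_equality(self):
        b1 = Bipartition({"c", "d"}, {"a", "b"})
        b2 = Bipartition({"b", "a"}, {"d", "c"})
        assert b1 == b2 and hash(b1) == hash(b2)
        assert b1.first == frozenset("ab")


class TestConsensus:
    def test_strict_idempotent(self):
        t = parse_newick("((a,b),c,(d,e));")
        assert bipartition_set(strict_consensus([t, t])) == bipartition_set(t)

    def test_strict_intersects(self):
        trees = [
            parse_newick("((a,b),(c,d),e);"),
            parse_newick("((a,b),(c,e),d);"),
            parse_newick("((a,b),c,(d,e));"),
        ]
        assert bipartition_set(strict_consensus(trees)) == {bip("ab", "cde")}

    def test_disjoint_splits_give_star(self):
        trees = [
            parse_newick("((a,b),(c,d),e);"),
            parse_newick("((a,c),(b,d),e);"),
        ]
        assert bipartition_set(strict_consensus(trees)) == frozenset()

    def test_majority_counting(self):
        trees = [
            parse_newick("((a,b),(c,d));"),
            parse_newick("((a,b),(c,d));"),
            parse_newick("((a,c),(b,d));"),
        ]
        assert bipartition_set(majority_rule_consensus(trees)) == {bip("ab", "cd")}

    def test_exact_half_excluded(self):
        trees = [
            parse_newick("((a,b),(c,d));"),
            parse_newick("((a,c),(b,d));"),
        ]
        assert bipartition_set(majority_rule_consensus(trees)) == frozenset()

    def test_threshold_one_matches_strict(self):
        trees = [
            parse_newick("((a,b),(c,d),e);"),
            parse_newick("((a,b),(c,e),d);"),
        ]
        maj = majority_rule_consensus(trees, threshold=0.999)
        assert bipartition_set(maj) == bipartition_set(strict_consensus(trees))

    def test_mismatched_leafsets_rejected(self):
        with pytest.raises(LeafSetMismatchError):
            strict_consensus(
                [parse_newick("((a,b),(c,d));"), parse_newick("((a,b),(c,e));")]
            )

    def test_split_support_fractions(self):
        trees = [
            parse_newick("((a,b),(c,d));"),
            parse_newick("((a,b),(c,d));"),
            parse_newick("((a,c),(b,d));"),
        ]
        support = split_support(trees)
        assert support[bip("ab", "cd")] == pytest.approx(2 / 3)


class TestRooting:
    def test_root_at_leaf_attachment(self):
        t = parse_newick("((a,b),c,(d,e));")
        rooted = root_at(t, "c")
        assert rooted.is_rooted
        assert leaf_labels(rooted) == {"a", "b", "d", "e"}
        from phyloterrace.trees import rooted_clusters

        assert rooted_clusters(rooted) == {frozenset("ab"), frozenset("de")}

    def test_root_then_unroot_recovers(self):
        t = parse_newick("(((a,b),c),(d,e),f);")
        back = reattach_leaf(root_at(t, "d"), "d")
        assert bipartition_set(back) == bipartition_set(t)

    def test_three_leaf_rooted_cherry(self):
        rooted = root_at(parse_newick("(a,b,c);"), "a")
        assert leaf_labels(rooted) == {"b", "c"}

    def test_unknown_label(self):
        with pytest.raises(UnknownLabelError):
            root_at(parse_newick("(a,b,c);"), "z")
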