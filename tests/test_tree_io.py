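import math

import pytest
from hypothesis import given, settings, strategies as st

from ptpdelim import (
    NewickError,
    TreeError,
    ml_delimit,
    parse_newick,
    root_longest_tip_edge,
    root_with_outgroup,
    write_newick,
)
from ptpdelim.simulate import simulate_dataset, SimulationConfig

from conftest import random_mixed_tree


class TestParse:
    def test_minimal_rooted_tree(self):
        t = parse_newick("((A:1,B:2):0.5,C:3);")
        assert t.n_tips == 3
        assert t.n_edges == 4
        assert not t.unrooted
        assert sorted(t.tip_labels()) == ["A", "B", "C"]

    def test_top_trifurcation_is_flagged_unrooted(self):
        t = parse_newick("(A:1,B:2,C:3);")
        assert t.unrooted
        with pytest.raises(TreeError, match="unrooted"):
            ml_delimit(t)

    @pytest.mark.parametrize(
        "text, match",
        [
            ("((A:1,B:2):0.5;", "character"),  # unbalanced parenthesis
            ("((A:1,B:2):0.5,C:3)", "character"),  # missing terminator
            ("((A:1,B):0.5,C:3);", "branch length"),  # missing length
            ("((A:1,A:2):0.5,C:3);", "duplicate"),
            ("((A:1,B:-2):0.5,C:3);", "negative"),
            ("((A:1,B:x):0.5,C:3);", "branch length"),
            ("", "empty"),
        ],
    )
    def test_malformed_input_is_rejected(self, text, match):
        with pytest.raises((NewickError, TreeError), match=match):
            parse_newick(text)

    def test_parse_error_reports_character_offset(self):
        with pytest.raises(NewickError) as exc:
            parse_newick("((A:1,B:2):0.5;")
        assert exc.value.offset is not None

    def test_quoted_labels_and_inner_labels_preserved(self):
        t = parse_newick("(('sp one':1,B:2)clade:0.5,C:3);")
        assert "sp one" in t.tip_labels()
        inner = [n for n in t.nodes if not n.is_tip and n.label]
        assert inner[0].label == "clade"
        assert "'sp one'" in write_newick(t)

    def test_zero_length_branches_accepted(self):
        t = parse_newick("((A:0.0,B:2):0.5,C:3);")
        assert t.n_edges == 4


class TestWrite:
    def test_round_trip_topology_labels_lengths(self):
        text = "((A:1,B:2):0.5,C:3);"
        again = write_newick(parse_newick(text))
        t2 = parse_newick(again)
        assert sorted(t2.tip_labels()) == ["A", "B", "C"]
        assert math.isclose(t2.total_length(), 6.5)

    def test_annotations_rendered_as_inner_labels(self):
        t = parse_newick("((A:1,B:2):0.5,C:3);")
        inner = next(n for n in t.nodes if not n.is_tip and n is not t.root)
        out = write_newick(t, {inner.id: 0.97})
        assert ")0.97:" in out

    def test_empty_annotation_map_is_plain_newick(self):
        t = parse_newick("((A:1,B:2):0.5,C:3);")
        assert write_newick(t, {}) == write_newick(t)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_round_trip_on_random_trees(self, seed):
        tree = random_mixed_tree(seed).tree
        t2 = parse_newick(write_newick(tree))
        assert sorted(t2.tip_labels()) == sorted(tree.tip_labels())
        assert math.isclose(t2.total_length(), tree.total_length(), rel_tol=1e-9)
        # same set of clades with same subtree lengths
        clades = lambda t: {
            t.subtree_tip_labels(n) for n in t.nodes
        }
        assert clades(t2) == clades(tree)

    def test_round_trip_against_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        text = write_newick(random_mixed_tree(5).tree)
        ref = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
        ours = parse_newick(text)
        assert sorted(x.taxon.label for x in ref.leaf_node_iter()) == sorted(
            ours.tip_labels()
        )
        assert math.isclose(
            sum(e.length for e in ref.edges() if e.length),
            ours.total_length(),
            rel_tol=1e-9,
        )


class TestPostorder:
    def test_children_precede_parents_and_root_is_last(self):
        tree = random_mixed_tree(11).tree
        seen = set()
        for node in tree.postorder():
            for child in node.children:
                assert child.id in seen
            seen.add(node.id)
        assert tree.nodes[-1] is tree.root
        assert len(seen) == len(tree.nodes)


class TestRooting:
    def test_longest_terminal_branch_split_at_midpoint(self):
        t = root_longest_tip_edge(parse_newick("(A:1,B:2,C:6);"))
        assert not t.unrooted
        c = next(n for n in t.nodes if n.label == "C")
        assert math.isclose(c.parent_edge_length, 3.0)
        assert math.isclose(t.total_length(), 9.0)
        assert len(t.root.children) == 2

    def test_already_rooted_tree_returned_unchanged(self):
        t = parse_newick("((A:1,B:2):0.5,C:3);")
        assert root_longest_tip_edge(t) is t

    def test_tie_broken_by_input_order(self):
        t = root_longest_tip_edge(parse_newick("(A:2,B:2,C:1);"))
        a = next(n for n in t.nodes if n.label == "A")
        assert a.parent is t.root
        assert math.isclose(a.parent_edge_length, 1.0)

    def test_too_few_tips_is_an_error(self):
        with pytest.raises(TreeError):
            root_longest_tip_edge(parse_newick("(A:1,B:2);"))

    def test_outgroup_rooting_on_existing_clade(self):
        t = root_with_outgroup(
            parse_newick("(A:1,B:2,(C:1,D:1):2);"), ["C", "D"]
        )
        assert not t.unrooted
        sides = [t.subtree_tip_labels(c) for c in t.root.children]
        assert frozenset({"C", "D"}) in sides
        assert math.isclose(t.total_length(), 7.0)

    def test_non_monophyletic_outgroup_rejected(self):
        with pytest.raises(TreeError, match="monophyletic"):
            root_with_outgroup(parse_newick("(A:1,B:2,(C:1,D:1):2);"), ["A", "C"])

    def test_unknown_outgroup_taxon_rejected(self):
        with pytest.raises(TreeError, match="Z"):
            root_with_outgroup(parse_newick("(A:1,B:2,(C:1,D:1):2);"), ["Z"])

    def test_outgroup_as_complement_side(self):
        # {A, B} is the complement of the CD clade: same separating edge
        t = root_with_outgroup(
            parse_newick("((A:1,B:2):0.5,C:1,D:2);"), ["C", "D"]
        )
        sides = [t.subtree_tip_labels(c) for c in t.root.children]
        assert frozenset({"C", "D"}) in sides

    def test_rooting_preserves_total_length_on_random_trees(self):
        for seed in range(5):
            ds = simulate_dataset(SimulationConfig(3, 3, 1.0, 40.0, seed=seed))
            og = sorted(ds.tree.subtree_tip_labels(ds.tree.root.children[0]))
            t2 = root_with_outgroup(ds.tree, og)
            assert math.isclose(
                t2.total_length(), ds.tree.total_length(), rel_tol=1e-9
            )
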