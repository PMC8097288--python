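"""Rooting, Fitch parsimony, Dollo loss counting, and tree annotation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from _oracles import (
    brute_force_dollo,
    brute_force_min_changes,
    shape_to_tree,
    tree_shapes,
)
from conftest import newick
from rniikit import (
    ROOT_EDGE,
    ReconstructionError,
    dollo_losses,
    fitch_reconstruct,
    map_losses,
    root_on_outgroup,
    simulate_tree,
    tip_labels,
)


def leafsets(tree):
    return {frozenset(l.taxon.label for l in c.leaf_iter())
            for c in tree.seed_node.child_nodes()}


class TestRootOnOutgroup:
    def test_roots_between_cherries(self):
        tree = newick("((a,b),(c,d));")
        rooted = root_on_outgroup(tree, {"a", "b"})
        assert leafsets(rooted) == {frozenset("ab"), frozenset("cd")}

    def test_single_tip_outgroup_roots_on_pendant_edge(self):
        tree = newick("(a,(b,(c,d)));")
        rooted = root_on_outgroup(tree, {"c"})
        assert frozenset("c") in leafsets(rooted)

    def test_non_monophyletic_outgroup_names_conflicts(self):
        tree = newick("((a,c),(b,d));")
        with pytest.raises(ReconstructionError, match="not monophyletic"):
            root_on_outgroup(tree, {"a", "b"})

    def test_input_tree_is_not_modified(self):
        tree = newick("(a,(b,(c,d)));")
        before = tree.as_string(schema="newick")
        root_on_outgroup(tree, {"c", "d"})
        assert tree.as_string(schema="newick") == before

    @pytest.mark.parametrize("seed", range(5))
    def test_random_trees_outgroup_monophyletic_after_rooting(self, seed):
        rng = np.random.default_rng(seed)
        tree = simulate_tree(12, rng=rng)
        # pick a clade of an arbitrary rooting as the outgroup
        internal = [
            n for n in tree.preorder_node_iter()
            if not n.is_leaf() and n is not tree.seed_node
        ]
        node = internal[int(rng.integers(len(internal)))]
        outgroup = {l.taxon.label for l in node.leaf_iter()}
        rooted = root_on_outgroup(tree, outgroup)
        assert frozenset(outgroup) in leafsets(rooted)
        assert set(tip_labels(rooted)) == set(tip_labels(tree))


def states_of(tree, pattern):
    tips = tip_labels(tree)
    return {
        t: ("active" if bit == "0" else "inactive")
        for t, bit in zip(tips, pattern)
    }


class TestFitch:
    def test_uniform_states_need_no_changes(self):
        tree = newick("((a,b),(c,d));")
        report = fitch_reconstruct(tree, {t: "active" for t in "abcd"})
        assert report.min_changes == 0 and not report.ambiguous

    def test_two_tip_disagreement_costs_one_and_is_ambiguous(self):
        tree = newick("(a,b);")
        report = fitch_reconstruct(tree, {"a": "active", "b": "inactive"})
        assert report.min_changes == 1
        assert report.ambiguous  # either root state is most parsimonious

    def test_matches_exhaustive_enumeration_on_small_trees(self):
        for n in (2, 3, 4, 5):
            for shape in tree_shapes(n):
                tree = shape_to_tree(shape, [f"t{i}" for i in range(n)])
                for bits in itertools.product("01", repeat=n):
                    states = states_of(tree, "".join(bits))
                    got = fitch_reconstruct(tree, states).min_changes
                    assert got == brute_force_min_changes(tree, states)

    def test_incomplete_states_rejected(self):
        tree = newick("(a,b);")
        with pytest.raises(ReconstructionError, match="mismatch"):
            fitch_reconstruct(tree, {"a": "active"})


class TestDollo:
    def test_single_inactive_clade_is_one_loss(self):
        tree = newick("((a,b),(c,d));")
        states = states_of(tree, "0011")
        report = dollo_losses(tree, states)
        assert report.n_independent_losses == 1
        assert not report.ambiguous

    def test_sister_inactive_tips_merge_to_stem_loss(self):
        tree = newick("(x,(a,b));")
        report = dollo_losses(tree, {"x": "active", "a": "inactive", "b": "inactive"})
        assert report.n_independent_losses == 1

    def test_inactive_tips_separated_by_active_need_two_losses(self):
        tree = newick("((a,b),(c,d));")
        report = dollo_losses(tree, states_of(tree, "1010"))
        assert report.n_independent_losses == 2

    def test_all_inactive_is_one_loss_on_root_edge(self):
        tree = newick("((a,b),(c,d));")
        report = dollo_losses(tree, states_of(tree, "1111"))
        assert report.n_independent_losses == 1
        assert report.loss_edges[0][0] == ROOT_EDGE

    def test_matches_exhaustive_enumeration_on_small_trees(self):
        for n in (2, 3, 4, 5):
            for shape in tree_shapes(n):
                tree = shape_to_tree(shape, [f"t{i}" for i in range(n)])
                for bits in itertools.product("01", repeat=n):
                    states = states_of(tree, "".join(bits))
                    got = dollo_losses(tree, states).n_independent_losses
                    assert got == brute_force_dollo(tree, states)

    def test_equals_maximal_inactive_clade_count(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            tree = simulate_tree(10, rng=rng)
            states = {
                t: ("inactive" if rng.random() < 0.4 else "active")
                for t in tip_labels(tree)
            }
            report = dollo_losses(tree, states)
            # count maximal all-inactive clades independently
            inactive = {}
            count = 0
            for node in tree.postorder_node_iter():
                if node.is_leaf():
                    inactive[node] = states[node.taxon.label] == "inactive"
                else:
                    inactive[node] = all(inactive[c] for c in node.child_nodes())
            for node in tree.preorder_node_iter():
                parent = node.parent_node
                if inactive[node] and (parent is None or not inactive[parent]):
                    count += 1
            assert report.n_independent_losses == count


class TestInvariantsAcrossModes:
    @pytest.mark.parametrize("seed", range(8))
    def test_fitch_never_exceeds_dollo(self, seed):
        rng = np.random.default_rng(seed)
        tree = simulate_tree(14, rng=rng)
        states = {
            t: ("inactive" if rng.random() < 0.5 else "active")
            for t in tip_labels(tree)
        }
        fitch = fitch_reconstruct(tree, states)
        dollo = dollo_losses(tree, states)
        assert fitch.min_changes <= dollo.min_changes

    def test_tip_relabelling_leaves_counts_unchanged(self):
        tree = newick("((a,b),(c,(d,e)));")
        states = {"a": "active", "b": "inactive", "c": "inactive",
                  "d": "active", "e": "inactive"}
        ref_fitch = fitch_reconstruct(tree, states).min_changes
        ref_dollo = dollo_losses(tree, states).n_independent_losses
        mapping = {"a": "w1", "b": "w2", "c": "w3", "d": "w4", "e": "w5"}
        tree2 = newick("((w1,w2),(w3,(w4,w5)));")
        states2 = {mapping[k]: v for k, v in states.items()}
        assert fitch_reconstruct(tree2, states2).min_changes == ref_fitch
        assert dollo_losses(tree2, states2).n_independent_losses == ref_dollo


class TestMapLosses:
    def features_for(self, states):
        return pd.DataFrame(
            [{"id": k, "active_site": v == "active", "nls": True,
              "cbk1_phospho_count": 0, "cbk1_docking": False}
             for k, v in states.items()]
        )

    def test_five_planted_non_nested_losses_recovered(self):
        tree = newick(
            "((a1,a2),((b1,(b2,b3)),((c1,c2),((d1,d2),((e1,e2),(f1,f2))))));"
        )
        inactive = {"a2", "b2", "b3", "c1", "d1", "d2", "f1"}
        states = {
            t: ("inactive" if t in inactive else "active")
            for t in tip_labels(tree)
        }
        report, annotated = map_losses(tree, self.features_for(states))
        assert report.n_independent_losses == 5
        text = annotated.as_string(schema="newick", suppress_annotations=False)
        assert text.count("loss=") == 5

    def test_zero_losses(self):
        tree = newick("((a,b),(c,d));")
        states = {t: "active" for t in "abcd"}
        report, _ = map_losses(tree, self.features_for(states))
        assert report.n_independent_losses == 0

    def test_id_mismatch_lists_symmetric_difference(self):
        tree = newick("((a,b),(c,d));")
        states = {t: "active" for t in "abce"}
        with pytest.raises(ReconstructionError, match="only in tree.*d.*only in table.*e"):
            map_losses(tree, self.features_for(states))
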