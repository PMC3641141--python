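"""Sankoff parsimony and Fritz-Purvis D against brute-force oracles."""

import itertools

import numpy as np
import pytest

import canopyphy as cp
from canopyphy.signal import unit_cost_matrix


def exhaustive_parsimony(tree: cp.Phylogeny, tip_states: dict, states,
                         cost):
    """Minimize total cost over every internal-node state labeling."""
    internal = [nd for nd in tree.tree.postorder_node_iter()
                if not nd.is_leaf()]
    best = np.inf
    lookup = {s: i for i, s in enumerate(states)}
    for assign in itertools.product(range(len(states)), repeat=len(internal)):
        state_of = {id(nd): a for nd, a in zip(internal, assign)}
        for lf in tree.tree.leaf_node_iter():
            state_of[id(lf)] = lookup[tip_states[lf.taxon.label]]
        total = 0.0
        for nd in tree.tree.preorder_node_iter():
            for child in nd.child_nodes():
                total += cost[state_of[id(nd)], state_of[id(child)]]
        best = min(best, total)
    return best


def fitch_length(tree: cp.Phylogeny, tip_states: dict) -> int:
    """Independent Fitch parsimony length for binary traits."""
    changes = 0
    sets = {}
    for nd in tree.tree.postorder_node_iter():
        if nd.is_leaf():
            sets[id(nd)] = {tip_states[nd.taxon.label]}
        else:
            acc = None
            for child in nd.child_nodes():
                s = sets[id(child)]
                if acc is None:
                    acc = s
                    continue
                if acc & s:
                    acc = acc & s
                else:
                    acc = acc | s
                    changes += 1
            sets[id(nd)] = acc
    return changes


class TestSankoffScore:
    def test_constant_trait_costs_nothing(self, eight_tip_tree):
        states = {t: "x" for t in eight_tip_tree.tip_labels}
        assert cp.sankoff_score(eight_tip_tree, states) == 0.0

    def test_two_tips_one_change(self):
        tree = cp.Phylogeny.from_newick("(a:1,b:1);")
        assert cp.sankoff_score(tree, {"a": 0, "b": 1}) == 1.0

    def test_matches_exhaustive_enumeration_three_states(self, eight_tip_tree):
        rng = np.random.default_rng(12)
        states = [0, 1, 2]
        cost = unit_cost_matrix(3)
        for _ in range(5):
            trait = {t: int(rng.integers(0, 3))
                     for t in eight_tip_tree.tip_labels}
            got = cp.sankoff_score(eight_tip_tree, trait, cost, states)
            want = exhaustive_parsimony(eight_tip_tree, trait, states, cost)
            assert got == want

    def test_weighted_costs_respected(self):
        tree = cp.Phylogeny.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        trait = {"a": 0, "b": 0, "c": 1, "d": 1}
        cost = np.array([[0.0, 5.0], [1.0, 0.0]])
        # one 0->1 change (cost 5) vs one 1->0 change (cost 1, root state 1)
        assert cp.sankoff_score(tree, trait, cost, states=[0, 1]) == 1.0

    def test_unit_binary_equals_fitch(self):
        for seed in range(4):
            tree, trait = cp.generate_tree(
                cp.TreeSimSpec(n_tips=24, prevalence=0.4, seed=seed))
            got = cp.sankoff_score(tree, trait)
            assert got == fitch_length(tree, trait)

    def test_bad_cost_matrix_rejected(self, eight_tip_tree):
        trait = {t: 0 for t in eight_tip_tree.tip_labels}
        with pytest.raises(ValueError):
            cp.sankoff_score(eight_tip_tree, trait,
                             np.array([[1.0, 1.0], [1.0, 0.0]]), [0, 1])


class TestSankoffSignalTest:
    def test_clade_partitioned_trait_is_significant(self, balanced16):
        trait = {t: int(t >= "t08") for t in balanced16.tip_labels}
        res = cp.sankoff_signal_test(balanced16, trait, n_perm=999, rng=0)
        assert res.score == 1.0
        assert res.p <= 0.01

    def test_score_invariant_trait_gives_p_one(self):
        # on a star tree every arrangement needs the same number of changes
        tree = cp.Phylogeny.from_newick("(a:1,b:1,c:1,d:1,e:1);")
        res = cp.sankoff_signal_test(tree, {"a": 1, "b": 0, "c": 0,
                                            "d": 0, "e": 0},
                                     n_perm=199, rng=0)
        assert res.p == 1.0

    def test_null_calibration_p_roughly_uniform(self, balanced16):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(60):
            labels = list(balanced16.tip_labels)
            ones = rng.choice(16, size=8, replace=False)
            trait = {t: int(i in set(ones)) for i, t in enumerate(labels)}
            ps.append(cp.sankoff_signal_test(balanced16, trait, n_perm=99,
                                             rng=rng).p)
        assert 0.35 < np.mean(ps) < 0.68

    def test_degenerate_trait_flagged(self, eight_tip_tree):
        trait = {t: 0 for t in eight_tip_tree.tip_labels}
        res = cp.sankoff_signal_test(eight_tip_tree, trait, n_perm=99, rng=0)
        assert np.isnan(res.p) and "degenerate" in res.flag


class TestFritzPurvisD:
    def test_pure_clade_trait_strongly_conserved(self, balanced16):
        trait = {t: int(t < "t04") for t in balanced16.tip_labels}
        res = cp.fritz_purvis_d(balanced16, trait, n_perm=500, rng=0)
        assert res.d < 0
        assert res.p_random <= 0.05

    def test_random_trait_near_one(self):
        ds = []
        for seed in range(20):
            tree, trait = cp.generate_tree(
                cp.TreeSimSpec(n_tips=64, trait_model="shuffle", seed=seed))
            ds.append(cp.fritz_purvis_d(tree, trait, n_perm=300,
                                        rng=100 + seed).d)
        assert np.mean(ds) == pytest.approx(1.0, abs=0.15)

    def test_brownian_trait_near_zero(self):
        ds = []
        for seed in range(20):
            tree, trait = cp.generate_tree(
                cp.TreeSimSpec(n_tips=64, trait_model="brownian_threshold",
                               seed=seed))
            ds.append(cp.fritz_purvis_d(tree, trait, n_perm=300,
                                        rng=200 + seed).d)
        assert np.mean(ds) == pytest.approx(0.0, abs=0.2)

    def test_invariant_to_tip_order_of_input(self, balanced16):
        rng = np.random.default_rng(9)
        trait = {t: int(rng.random() < 0.5) for t in balanced16.tip_labels}
        shuffled = dict(sorted(trait.items(), key=lambda kv: hash(kv[0])))
        a = cp.fritz_purvis_d(balanced16, trait, n_perm=99, rng=5)
        b = cp.fritz_purvis_d(balanced16, shuffled, n_perm=99, rng=5)
        assert a.d == b.d and a.p_random == b.p_random

    def test_constant_trait_flagged(self, balanced16):
        trait = {t: 1 for t in balanced16.tip_labels}
        res = cp.fritz_purvis_d(balanced16, trait, n_perm=99, rng=0)
        assert np.isnan(res.d) and res.flag == "constant trait"


class TestEstimators:
    def test_sklearn_contract(self, balanced16):
        from sklearn.base import clone
        est = cp.DStatistic(n_perm=99, random_state=1)
        est2 = clone(est)
        trait = {t: int(t < "t08") for t in balanced16.tip_labels}
        d1 = est.fit(balanced16, trait).d_
        d2 = est2.fit(balanced16, trait).d_
        assert d1 == d2
        sk = cp.SankoffSignal(n_perm=99, random_state=1).fit(balanced16, trait)
        assert sk.score_ == 1.0 and 0.0 < sk.p_ <= 1.0
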