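"""Faith's PD, MPD/MNTD, S.E.S. PD and NRI/NTI against independent oracles."""

import itertools

import dendropy
import numpy as np
import pytest

import canopyphy as cp

from conftest import brute_force_pd


class TestFaithPd:
    def test_all_tips_gives_total_branch_length(self, eight_tip_tree):
        assert cp.faith_pd(eight_tip_tree, eight_tip_tree.tip_labels) \
            == pytest.approx(eight_tip_tree.total_branch_length)

    def test_two_tip_ultrametric_closed_form(self):
        tree = cp.Phylogeny.from_newick("(a:3.5,b:3.5);")
        assert cp.faith_pd(tree, ["a", "b"]) == pytest.approx(7.0)
        assert cp.faith_pd(tree, ["a"]) == pytest.approx(3.5)  # root path
        assert cp.faith_pd(tree, ["a"], rooted=False) == pytest.approx(0.0)

    def test_all_255_subsets_match_union_of_root_paths(self, eight_tip_tree):
        labels = eight_tip_tree.tip_labels
        for k in range(1, 9):
            for sub in itertools.combinations(labels, k):
                got = cp.faith_pd(eight_tip_tree, sub)
                want = brute_force_pd(eight_tip_tree, sub)
                assert got == pytest.approx(want), sub

    def test_unrooted_subsets_match_oracle(self, eight_tip_tree):
        labels = eight_tip_tree.tip_labels
        rng = np.random.default_rng(0)
        for _ in range(40):
            k = rng.integers(1, 9)
            sub = list(rng.choice(labels, size=k, replace=False))
            got = cp.faith_pd(eight_tip_tree, sub, rooted=False)
            assert got == pytest.approx(brute_force_pd(eight_tip_tree, sub,
                                                       rooted=False))

    def test_monotone_under_inclusion(self, eight_tip_tree):
        rng = np.random.default_rng(1)
        labels = eight_tip_tree.tip_labels
        for _ in range(30):
            a = set(rng.choice(labels, size=3, replace=False))
            b = a | set(rng.choice(labels, size=3, replace=False))
            assert cp.faith_pd(eight_tip_tree, a) \
                <= cp.faith_pd(eight_tip_tree, b) + 1e-12

    def test_unknown_species_named_in_error(self, eight_tip_tree):
        with pytest.raises(KeyError, match="nosuch"):
            cp.faith_pd(eight_tip_tree, ["nosuch"])


class TestMpdMntd:
    def test_pair_equals_patristic_distance(self):
        tree = cp.Phylogeny.from_newick("((a:1,b:2):3,c:4);")
        assert cp.mpd(tree, ["a", "b"]) == pytest.approx(3.0)
        assert cp.mntd(tree, ["a", "b"]) == pytest.approx(3.0)
        assert cp.mpd(tree, ["a", "c"]) == pytest.approx(8.0)

    def test_cherry_closed_form(self, balanced16):
        # adjacent tips of the balanced tree form a cherry: mntd = 2x1
        assert cp.mntd(balanced16, ["t00", "t01"]) == pytest.approx(2.0)

    def test_random_subsets_match_dendropy_patristic(self):
        tree, _ = cp.generate_tree(cp.TreeSimSpec(n_tips=16, seed=3))
        pdm = tree.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.tree.taxon_namespace}
        rng = np.random.default_rng(4)
        for _ in range(10):
            sub = list(rng.choice(tree.tip_labels, size=5, replace=False))
            pairs = list(itertools.combinations(sub, 2))
            d = {p: pdm.patristic_distance(taxa[p[0]], taxa[p[1]])
                 for p in pairs}
            want_mpd = np.mean(list(d.values()))
            want_mntd = np.mean([
                min(v for p, v in d.items() if s in p) for s in sub])
            assert cp.mpd(tree, sub) == pytest.approx(want_mpd)
            assert cp.mntd(tree, sub) == pytest.approx(want_mntd)

    def test_singleton_rejected(self, eight_tip_tree):
        with pytest.raises(ValueError):
            cp.mpd(eight_tip_tree, [eight_tip_tree.tip_labels[0]])


class TestNriNti:
    def test_clustered_set_positive(self, balanced16):
        nri, nti = cp.nri_nti(balanced16, ["t00", "t01", "t02", "t03"],
                              n_shuffle=499, rng=0)
        assert nri > 0 and nti > 0

    def test_overdispersed_set_negative(self, balanced16):
        nri, _ = cp.nri_nti(balanced16, ["t00", "t04", "t08", "t12"],
                            n_shuffle=499, rng=0)
        assert nri < 0

    def test_matches_exhaustive_subset_null(self):
        tree = cp.Phylogeny.from_newick(
            "(((a:1,b:1):1,(c:1,d:1):1):1,(e:2,f:2):1);")
        subset = ["a", "b"]
        obs = cp.mpd(tree, subset)
        null = [cp.mpd(tree, list(pair))
                for pair in itertools.combinations(tree.tip_labels, 2)]
        want = -(obs - np.mean(null)) / np.std(null, ddof=1)
        nri, _ = cp.nri_nti(tree, subset, n_shuffle=4999, rng=1)
        assert nri == pytest.approx(want, abs=0.15)

    def test_full_tip_set_undefined(self, balanced16):
        nri, nti = cp.nri_nti(balanced16, balanced16.tip_labels,
                              n_shuffle=99, rng=0)
        assert np.isnan(nri) and np.isnan(nti)

    def test_random_subsets_center_on_zero(self, balanced16):
        rng = np.random.default_rng(5)
        vals = []
        for _ in range(40):
            sub = list(rng.choice(balanced16.tip_labels, size=5,
                                  replace=False))
            nri, _ = cp.nri_nti(balanced16, sub, n_shuffle=99, rng=rng)
            vals.append(nri)
        assert abs(np.mean(vals)) < 0.35  # ~2.2 MC standard errors


@pytest.fixture(scope="module")
def ipar_setup():
    stems = [cp.TreeRecord("f1", "F", 60.0, 60.0, 2.0),
                 cp.TreeRecord("x1", "A", 62.0, 60.0, 2.0),
                 cp.TreeRecord("x2", "B", 63.0, 60.0, 2.0),
             cp.TreeRecord("x3", "C", 90.0, 90.0, 2.0)]
    plot = cp.CensusPlot((0, 0, 120, 120), stems)
    tree = cp.Phylogeny.from_newick("((A:1,B:1):2,(C:2,F:2):1);")
    return plot, tree


class TestIparObserved:
    def test_single_focal_matches_faith_pd(self, ipar_setup):
        plot, tree = ipar_setup
        curve, n = cp.ipar_observed(plot, tree, "F", radii=[5.0],
                                    buffer=50.0)
        assert n == 1
        assert curve[0] == pytest.approx(cp.faith_pd(tree, ["A", "B"]))

    def test_empty_neighborhood_scores_zero(self, ipar_setup):
        plot, tree = ipar_setup
        curve, _ = cp.ipar_observed(plot, tree, "F", radii=[1.0],
                                    buffer=50.0)
        assert curve[0] == 0.0

    def test_matches_per_focal_recomputation(self, csr_plot):
        tree, _ = cp.generate_tree(cp.TreeSimSpec(n_tips=10, seed=9))
        relabel = dict(zip(tree.tip_labels, csr_plot.species_ids))
        for leaf in tree.tree.leaf_node_iter():
            leaf.taxon.label = relabel[leaf.taxon.label]
        tree = cp.Phylogeny(tree.tree)
        radii = np.array([5.0, 15.0])
        curve, _ = cp.ipar_observed(csr_plot, tree, "sp01", radii=radii,
                                    buffer=40.0)
        foc = cp.eligible_focals(csr_plot, "sp01", 40.0)
        want = np.zeros(2)
        for i in foc:
            for k, r in enumerate(radii):
                nb = cp.neighborhood_species(csr_plot, int(i), float(r))
                want[k] += cp.faith_pd(tree, nb) if nb else 0.0
        assert curve == pytest.approx(want / foc.size)


class TestSesPd:
    def test_exhaustive_four_species_null(self):
        # plot with one focal and neighborhoods {A}, {A,B} at r=3,6
        stems = [cp.TreeRecord("f1", "F", 30.0, 30.0, 2.0),
                 cp.TreeRecord("a1", "A", 32.0, 30.0, 2.0),
                 cp.TreeRecord("b1", "B", 35.0, 30.0, 2.0),
                 cp.TreeRecord("c1", "C", 50.0, 50.0, 2.0)]
        plot = cp.CensusPlot((0, 0, 60, 60), stems)
        tree = cp.Phylogeny.from_newick("((A:1,B:2.5):2,(C:2,F:3):1);")
        res = cp.ses_pd(plot, tree, "F", radii=[3.0, 6.0], n_shuffle=999,
                        buffer=20.0, rng=0)
        # exact null: PD of singleton / pair under all 24 label permutations
        labels = tree.tip_labels
        exact = {1: [], 2: []}
        for perm in itertools.permutations(labels):
            pos = {lab: labels[i] for i, lab in enumerate(perm)}
            exact[1].append(cp.faith_pd(tree, [pos["A"]]))
            exact[2].append(cp.faith_pd(tree, [pos["A"], pos["B"]]))
        for r, size in zip(res, (1, 2)):
            want = (r.observed_pd - np.mean(exact[size])) \
                / np.std(exact[size], ddof=1)
            assert r.ses == pytest.approx(want, abs=0.2)

    def test_observed_at_null_mean_gives_zero(self):
        # star tree: every permutation yields the same PD -> sd 0, flagged
        stems = [cp.TreeRecord("f1", "F", 30.0, 30.0, 2.0),
                 cp.TreeRecord("a1", "A", 32.0, 30.0, 2.0)]
        plot = cp.CensusPlot((0, 0, 60, 60), stems)
        tree = cp.Phylogeny.from_newick("(A:1,B:1,F:1);")
        res = cp.ses_pd(plot, tree, "F", radii=[3.0], n_shuffle=99,
                        buffer=20.0, rng=0)
        assert res[0].status == cp.NEUTRAL
        assert "degenerate" in res[0].flag

    def test_extreme_observation_is_phylogenetic_accumulator(self):
        # neighborhood = the pair of tips with maximal PD on a generic
        # (non-ultrametric) tree, so the maximum is unique and ties rare
        tree, _ = cp.generate_tree(cp.TreeSimSpec(n_tips=12, seed=21))
        jitter = np.random.default_rng(22)
        for nd in tree.tree.preorder_node_iter():
            if nd.edge.length:
                nd.edge.length *= jitter.uniform(0.5, 1.5)
        tree = cp.Phylogeny(tree.tree)
        pairs = {(a, b): cp.faith_pd(tree, [a, b])
                 for a, b in itertools.combinations(tree.tip_labels, 2)}
        (best_a, best_b), _ = max(pairs.items(), key=lambda kv: kv[1])
        focal = next(t for t in tree.tip_labels if t not in (best_a, best_b))
        stems = [cp.TreeRecord("f1", focal, 30.0, 30.0, 2.0),
                 cp.TreeRecord("a1", best_a, 31.0, 30.0, 2.0),
                 cp.TreeRecord("b1", best_b, 32.0, 30.0, 2.0)]
        plot = cp.CensusPlot((0, 0, 60, 60), stems)
        res = cp.ses_pd(plot, tree, focal, radii=[5.0], n_shuffle=999,
                        buffer=20.0, rng=1)
        assert res[0].ses > 0
        assert res[0].status == cp.ACCUMULATOR

    def test_minimum_shuffles_enforced(self, csr_plot, eight_tip_tree):
        with pytest.raises(ValueError):
            cp.ses_pd(csr_plot, eight_tip_tree, "sp01", n_shuffle=10)


class TestBrownian:
    def test_tip_variance_scales_with_depth(self):
        tree = cp.Phylogeny.from_newick("(a:1,b:9);")
        vals = cp.simulate_brownian(tree, 4000, rng=0)
        va, vb = vals.var(axis=0)
        assert va == pytest.approx(1.0, rel=0.15)
        assert vb == pytest.approx(9.0, rel=0.15)
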