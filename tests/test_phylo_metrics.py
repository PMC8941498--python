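"""Metric correctness against hand computations and brute-force oracles."""

import math

import numpy as np
import pytest

import oracles
from phylorefugia import phylo_metrics as pm
from phylorefugia import synthetic_data as sd
from phylorefugia.grid_assembly import CommunityMatrix, GridSpec


class TestNewickIO:
    def test_two_tip_tree_distance(self):
        tree = pm.parse_newick("(A:1,B:1):0;")
        dm = pm.cophenetic_distances(tree)
        assert dm.matrix[0, 1] == pytest.approx(2.0)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            pm.parse_newick("(A:1,A:1);")

    def test_malformed_newick_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            pm.parse_newick("((A:1,B:1;")

    def test_missing_branch_length_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            pm.parse_newick("(A,B:1);")

    def test_roundtrip_preserves_metrics(self, random_trees, tmp_path):
        for i, tree in enumerate(random_trees):
            path = tmp_path / f"t{i}.nwk"
            pm.write_newick(tree, path)
            back = pm.read_newick(path)
            d1 = pm.cophenetic_distances(tree)
            d2 = pm.cophenetic_distances(back)
            assert d1.labels == d2.labels
            np.testing.assert_allclose(d1.matrix, d2.matrix, rtol=1e-10)


class TestCopheneticDistances:
    def test_hand_computed_three_tips(self, three_tip_tree):
        dm = pm.cophenetic_distances(three_tip_tree)
        assert dm.labels == ("A", "B", "C")
        np.testing.assert_allclose(
            dm.matrix, [[0, 2, 4], [2, 0, 4], [4, 4, 0]], atol=1e-12
        )

    def test_matches_path_walking_oracle(self, random_trees):
        for tree in random_trees[:6]:
            dm = pm.cophenetic_distances(tree)
            for i in range(len(dm.labels)):
                for j in range(i + 1, len(dm.labels)):
                    expect = oracles.path_distance(tree, dm.labels[i], dm.labels[j])
                    assert dm.matrix[i, j] == pytest.approx(expect, rel=1e-12)

    def test_matches_dendropy_distance_matrix(self, random_trees):
        # independent library route
        tree = random_trees[3]
        dm = pm.cophenetic_distances(tree)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(dm.labels):
            for j in range(i + 1, len(dm.labels)):
                expect = pdm.patristic_distance(taxa[a], taxa[dm.labels[j]])
                assert dm.matrix[i, j] == pytest.approx(expect, rel=1e-10)


class TestCommunityMetrics:
    def test_hand_computed_values(self, three_tip_tree):
        dm = pm.cophenetic_distances(three_tip_tree)
        assert pm.mpd(["A", "B"], dm) == pytest.approx(2.0)
        assert pm.mpd(["A", "B", "C"], dm) == pytest.approx(10 / 3)
        assert pm.mntd(["A", "B", "C"], dm) == pytest.approx(8 / 3)
        assert pm.mntd(["A", "B"], dm) == pm.mpd(["A", "B"], dm)
        assert pm.faith_pd(["A", "B"], three_tip_tree) == pytest.approx(2.0)
        assert pm.faith_pd(["A", "B", "C"], three_tip_tree) == pytest.approx(5.0)

    def test_singletons_and_empties_are_missing(self, three_tip_tree):
        dm = pm.cophenetic_distances(three_tip_tree)
        assert math.isnan(pm.mpd(["A"], dm))
        assert math.isnan(pm.mntd(["A"], dm))
        assert pm.faith_pd(["A"], three_tip_tree) == 0.0
        assert math.isnan(pm.faith_pd([], three_tip_tree))

    def test_root_inclusive_pd_adds_stem(self, three_tip_tree):
        # union of root-to-tip paths: A(1) + B(1) + shared stem (1)
        assert pm.faith_pd(["A", "B"], three_tip_tree, include_root=True) == (
            pytest.approx(3.0)
        )
        # singleton: tip-to-root path instead of 0
        assert pm.faith_pd(["C"], three_tip_tree, include_root=True) == (
            pytest.approx(2.0)
        )

    def test_oracle_equivalence_many_instances(self, random_trees):
        """MPD/MNTD/PD equal brute-force oracles over >=1000 random
        (tree, community) instances, to 1e-12 relative."""
        rng = np.random.default_rng(42)
        count = 0
        for tree in random_trees:
            dm = pm.cophenetic_distances(tree)
            labels = list(dm.labels)
            for _ in range(90):
                size = rng.integers(2, len(labels) + 1)
                comm = sorted(rng.choice(labels, size=size, replace=False))
                assert pm.mpd(comm, dm) == pytest.approx(
                    oracles.mpd_double_loop(comm, dm), rel=1e-12
                )
                assert pm.mntd(comm, dm) == pytest.approx(
                    oracles.mntd_double_loop(comm, dm), rel=1e-12
                )
                assert pm.faith_pd(comm, tree) == pytest.approx(
                    oracles.faith_pd_edge_union(comm, tree), rel=1e-12
                )
                count += 1
        assert count >= 1000

    def test_invariants_mntd_le_mpd_and_pd_monotone(self, random_trees):
        rng = np.random.default_rng(7)
        for tree in random_trees:
            dm = pm.cophenetic_distances(tree)
            labels = list(dm.labels)
            for _ in range(40):
                size = rng.integers(2, len(labels))
                comm = sorted(rng.choice(labels, size=size, replace=False))
                assert pm.mntd(comm, dm) <= pm.mpd(comm, dm) + 1e-12
                extra = rng.choice([l for l in labels if l not in comm])
                assert pm.faith_pd(comm + [extra], tree) >= pm.faith_pd(comm, tree) - 1e-12

    def test_linear_scaling_of_all_metrics(self, random_trees):
        tree = random_trees[4]
        scaled = sd.gen_posterior_set(tree, 1, 0.0, seed=0)[0]
        for nd in scaled.preorder_node_iter():
            if nd.parent_node is not None:
                nd.edge.length *= 3.0
        dm, dms = pm.cophenetic_distances(tree), pm.cophenetic_distances(scaled)
        comm = list(dm.labels[:5])
        assert pm.mpd(comm, dms) == pytest.approx(3 * pm.mpd(comm, dm), rel=1e-12)
        assert pm.mntd(comm, dms) == pytest.approx(3 * pm.mntd(comm, dm), rel=1e-12)
        assert pm.faith_pd(comm, scaled) == pytest.approx(
            3 * pm.faith_pd(comm, tree), rel=1e-12
        )


class TestSummarizeOverTrees:
    @pytest.fixture()
    def matrix_and_trees(self):
        tree = sd.gen_tree(12, 1.0, 0.2, seed=11)
        trees = sd.gen_posterior_set(tree, 8, 0.15, seed=3)
        grid = GridSpec(0, 0, 0.5, 0.4, 0.1)
        rng = np.random.default_rng(5)
        labels = tuple(sorted(lf.taxon.label for lf in tree.leaf_node_iter()))
        mat = (rng.random((grid.n_cells, len(labels))) < 0.4).astype(np.int8)
        return CommunityMatrix(grid=grid, species=labels, matrix=mat), tree, trees

    @pytest.mark.parametrize("metric", ["mpd", "mntd", "pd"])
    def test_vectorised_cells_match_per_community_functions(
        self, matrix_and_trees, metric
    ):
        cm, tree, _ = matrix_and_trees
        surf = pm.summarize_over_trees(cm, [tree], metric)
        dm = pm.cophenetic_distances(tree)
        for c in range(cm.grid.n_cells):
            comm = [s for s, v in zip(cm.species, cm.matrix[c]) if v]
            if metric == "mpd":
                expect = pm.mpd(comm, dm) if len(comm) >= 2 else math.nan
            elif metric == "mntd":
                expect = pm.mntd(comm, dm) if len(comm) >= 2 else math.nan
            else:
                expect = pm.faith_pd(comm, tree) if comm else math.nan
            if math.isnan(expect):
                assert math.isnan(surf.values[c])
            else:
                assert surf.values[c] == pytest.approx(expect, rel=1e-12)

    def test_single_tree_mean_equals_min_equals_max(self, matrix_and_trees):
        cm, tree, _ = matrix_and_trees
        surf = pm.summarize_over_trees(cm, [tree], "pd")
        m = surf.mask
        np.testing.assert_allclose(surf.values[m], surf.vmin[m])
        np.testing.assert_allclose(surf.values[m], surf.vmax[m])

    def test_scaled_tree_pair_gives_1p5x_mean(self, matrix_and_trees):
        cm, tree, _ = matrix_and_trees
        doubled = sd.gen_posterior_set(tree, 1, 0.0, seed=0)[0]
        for nd in doubled.preorder_node_iter():
            if nd.parent_node is not None:
                nd.edge.length *= 2.0
        one = pm.summarize_over_trees(cm, [tree], "mpd")
        both = pm.summarize_over_trees(cm, [tree, doubled], "mpd")
        m = one.mask
        np.testing.assert_allclose(both.values[m], 1.5 * one.values[m], rtol=1e-12)

    def test_mean_within_range_over_jittered_trees(self, matrix_and_trees):
        cm, _, trees = matrix_and_trees
        surf = pm.summarize_over_trees(cm, trees, "mntd")
        m = surf.mask
        assert (surf.vmin[m] - 1e-12 <= surf.values[m]).all()
        assert (surf.values[m] <= surf.vmax[m] + 1e-12).all()

    def test_missing_species_raises(self, matrix_and_trees):
        cm, tree, _ = matrix_and_trees
        bad = CommunityMatrix(
            grid=cm.grid,
            species=cm.species[:-1] + ("not_a_tip",),
            matrix=cm.matrix,
        )
        with pytest.raises(KeyError, match="not_a_tip"):
            pm.summarize_over_trees(bad, [tree], "pd")
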