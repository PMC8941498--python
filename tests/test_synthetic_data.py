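"""Generator contracts: determinism, ultrametricity, jitter statistics,
partitions, and the planted refugium clustering signal."""

import numpy as np
import pytest
from shapely.geometry import Point

import oracles
from phylorefugia import phylo_metrics as pm
from phylorefugia import synthetic_data as sd
from phylorefugia.grid_assembly import GridSpec


class TestGenTree:
    def test_two_tips_ultrametric(self):
        tree = sd.gen_tree(2, 1.0, 0.0, seed=0)
        depths = [lf.distance_from_root() for lf in tree.leaf_node_iter()]
        assert depths[0] == pytest.approx(depths[1], rel=1e-9)

    def test_requested_tip_count_and_positive_lengths(self):
        tree = sd.gen_tree(20, 1.2, 0.4, seed=5)
        assert len(tree.leaf_nodes()) == 20
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None:
                assert nd.edge.length > 0

    def test_deterministic_newick(self):
        a = pm.tree_to_newick_string(sd.gen_tree(10, 1.0, 0.2, seed=3))
        b = pm.tree_to_newick_string(sd.gen_tree(10, 1.0, 0.2, seed=3))
        assert a == b

    @pytest.mark.parametrize("kwargs", [
        dict(n_tips=1), dict(death_rate=1.5), dict(birth_rate=0.0),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(n_tips=5, birth_rate=1.0, death_rate=0.0, seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            sd.gen_tree(**base)

    def test_mean_depth_matches_pure_birth_oracle(self):
        """Root-to-tip depth of conditioned pure-birth trees agrees with a
        count-level Monte-Carlo oracle within 3 combined standard errors."""
        lam, n = 1.0, 12
        depths = [
            max(lf.distance_from_root() for lf in sd.gen_tree(n, lam, 0.0, seed=s).leaf_node_iter())
            for s in range(300)
        ]
        rng = np.random.default_rng(99)
        oracle = [oracles.yule_attainment_time(n, lam, rng) for _ in range(20000)]
        se = np.sqrt(np.var(depths) / len(depths) + np.var(oracle) / len(oracle))
        assert abs(np.mean(depths) - np.mean(oracle)) < 3 * se


class TestPosteriorSet:
    def test_zero_jitter_returns_identical_metrics(self, random_trees):
        tree = random_trees[2]
        clones = sd.gen_posterior_set(tree, 5, 0.0, seed=1)
        base = pm.cophenetic_distances(tree).matrix
        for c in clones:
            np.testing.assert_allclose(pm.cophenetic_distances(c).matrix, base)

    def test_mean_branch_length_near_original(self):
        tree = sd.gen_tree(20, 1.0, 0.0, seed=2)
        clones = sd.gen_posterior_set(tree, 100, 0.1, seed=4)
        orig = np.array([
            nd.edge.length for nd in tree.preorder_node_iter() if nd.parent_node
        ])
        stacked = np.array([
            [nd.edge.length for nd in c.preorder_node_iter() if nd.parent_node]
            for c in clones
        ])
        # lognormal(0, 0.1) has mean exp(0.005) ~ 1.005; 5% tolerance
        np.testing.assert_allclose(stacked.mean(axis=0), orig, rtol=0.05)

    def test_t_zero_rejected(self, random_trees):
        with pytest.raises(ValueError):
            sd.gen_posterior_set(random_trees[0], 0, 0.1, seed=0)


class TestEcoregions:
    def test_single_region_and_one_per_cell_boundaries(self, small_grid):
        assert sd.gen_ecoregions(small_grid, 1, seed=0).n_regions == 1
        full = sd.gen_ecoregions(small_grid, small_grid.n_cells, seed=0)
        assert full.n_regions == small_grid.n_cells

    def test_partition_covers_all_cells_once(self, small_grid):
        eco = sd.gen_ecoregions(small_grid, 7, seed=3)
        assert len(eco.region_of) == small_grid.n_cells
        counts = np.bincount(eco.region_of)
        assert counts.sum() == small_grid.n_cells
        assert (counts > 0).all()

    def test_regions_are_contiguous(self, small_grid):
        eco = sd.gen_ecoregions(small_grid, 5, seed=8)
        nx, ny = small_grid.nx, small_grid.ny
        lab = eco.region_of.reshape(ny, nx)
        for rid in np.unique(lab):
            cells = set(zip(*np.nonzero(lab == rid)))
            start = next(iter(cells))
            seen = {start}
            stack = [start]
            while stack:
                y, x = stack.pop()
                for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    nb = (y + dy, x + dx)
                    if nb in cells and nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            assert seen == cells

    def test_k_out_of_bounds_rejected(self, small_grid):
        with pytest.raises(ValueError):
            sd.gen_ecoregions(small_grid, 0, seed=0)
        with pytest.raises(ValueError):
            sd.gen_ecoregions(small_grid, small_grid.n_cells + 1, seed=0)


class TestGenRanges:
    @pytest.fixture()
    def setup(self):
        grid = GridSpec(0, 0, 3.0, 2.0, 0.1)
        refug = Point(0.8, 0.8).buffer(0.5, quad_segs=32)
        tree = sd.gen_tree(40, 1.0, 0.5, seed=21)
        return grid, refug, tree

    def test_full_clustering_confines_refugium_to_one_clade(self, setup):
        grid, refug, tree = setup
        ranges = sd.gen_ranges(tree, grid, refug, 1.0, 1.0, seed=2)
        dm = pm.cophenetic_distances(tree)
        in_ref = [sp for sp, r in ranges.items() if refug.covers(r.centroid)]
        assert len(in_ref) >= 2
        assert pm.mpd(in_ref, dm) <= pm.mpd_from_matrix(dm.matrix)
        clade = sd._tightest_covering_clade(tree, len(in_ref))
        assert set(in_ref) <= set(clade)

    def test_no_clustering_leaves_no_phylogenetic_signal(self, setup):
        """At strength 0 the refugium-centered species are a random subset:
        their MPD matches outside species over repeated worlds."""
        grid, refug, tree = setup
        dm = pm.cophenetic_distances(tree)
        diffs = []
        for seed in range(40):
            ranges = sd.gen_ranges(tree, grid, refug, 0.0, 1.0, seed=seed)
            in_ref = [sp for sp, r in ranges.items() if refug.covers(r.centroid)]
            out = [sp for sp in ranges if sp not in in_ref]
            if len(in_ref) >= 2:
                diffs.append(pm.mpd(in_ref, dm) - pm.mpd(out, dm))
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se

    def test_every_polygon_intersects_domain(self, setup):
        grid, refug, tree = setup
        import shapely

        domain = shapely.box(grid.x_min, grid.y_min, grid.x_max, grid.y_max)
        ranges = sd.gen_ranges(tree, grid, refug, 0.5, 1.0, seed=5)
        labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        assert sorted(ranges) == labels
        for poly in ranges.values():
            assert poly.intersects(domain)
            assert poly.area > 0

    def test_refugium_outside_domain_rejected(self, setup):
        grid, _, tree = setup
        far = Point(10, 10).buffer(0.5)
        with pytest.raises(ValueError, match="refugium"):
            sd.gen_ranges(tree, grid, far, 0.5, 1.0, seed=0)

    def test_bad_clustering_strength_rejected(self, setup):
        grid, refug, tree = setup
        with pytest.raises(ValueError):
            sd.gen_ranges(tree, grid, refug, 1.5, 1.0, seed=0)


class TestGenWorld:
    @staticmethod
    def _richness_correlations(cfg, n_worlds):
        from phylorefugia import grid_assembly as ga

        corrs = []
        for seed in range(n_worlds):
            world = sd.gen_world(cfg, seed=seed)
            ra = ga.richness(world.community_matrix("A")).values
            rb = ga.richness(world.community_matrix("B")).values
            corrs.append(np.corrcoef(ra, rb)[0, 1])
        return np.array(corrs)

    def test_shared_field_correlates_group_richness(self):
        corrs = self._richness_correlations(
            sd.WorldConfig(n_trees=1), n_worlds=20
        )
        assert (corrs > 0.5).mean() >= 0.95
        assert np.median(corrs) > 0.6

    def test_independent_fields_remove_correlation(self):
        cfg = sd.WorldConfig(
            n_trees=1, shared_field_weight=0.0, clustering_strength=0.0,
            habitat_exclusion=0.0, refugium_fraction=0.0,
        )
        corrs = self._richness_correlations(cfg, n_worlds=20)
        assert abs(np.median(corrs)) < 0.25
        se = corrs.std(ddof=1) / np.sqrt(len(corrs))
        assert abs(corrs.mean()) < 3 * se + 0.1

    def test_same_seed_serializes_byte_identical(self, tmp_path):
        cfg = sd.WorldConfig(
            x_max=1.5, y_max=1.0, n_species_a=12, n_species_b=12, n_trees=3,
            k_ecoregions=4, refugium_x=0.5, refugium_y=0.5, refugium_radius=0.3,
        )
        out1, out2 = tmp_path / "w1", tmp_path / "w2"
        sd.gen_world(cfg, seed=11).save(out1)
        sd.gen_world(cfg, seed=11).save(out2)
        files1 = sorted(p.name for p in out1.iterdir())
        assert files1 == sorted(p.name for p in out2.iterdir())
        for name in files1:
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_groups_share_grid_and_ecoregions(self, tiny_world):
        assert set(tiny_world.groups) == {"A", "B"}
        assert len(tiny_world.ecoregions.region_of) == tiny_world.grid.n_cells
        for g in tiny_world.groups.values():
            assert len(g.trees) == 5
            tips = {lf.taxon.label for lf in g.tree.leaf_node_iter()}
            assert set(g.ranges) == tips
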