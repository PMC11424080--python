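import numpy as np
import pandas as pd
import pytest

from stagediv import homology, phylo
from stagediv.specificity import ks_two_sample
from stagediv.synthetic_data import (SimulationConfig, evolve_profiles,
                                     generate_dataset, make_hits,
                                     simulate_gene_tree)


class TestYuleTrees:
    def test_same_seed_same_newick(self):
        t1 = simulate_gene_tree(6, 1.0, seed=42)
        t2 = simulate_gene_tree(6, 1.0, seed=42)
        assert t1.as_newick() == t2.as_newick()

    @pytest.mark.parametrize("n", [2, 3, 5, 9])
    def test_rooted_binary_branch_count(self, n):
        tree = simulate_gene_tree(n, 1.0, seed=1)
        assert len(tree.edges()) == 2 * n - 2

    def test_depth_decreases_with_birth_rate(self, rng):
        def mean_depth(rate):
            depths = []
            for _ in range(200):
                tree = simulate_gene_tree(4, rate, seed=rng)
                dm = phylo.patristic_distances(tree)
                depths.append(dm.values.max() / 2)
            return np.mean(depths)
        assert mean_depth(4.0) < mean_depth(0.5)

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError):
            simulate_gene_tree(1, 1.0, seed=0)


class TestBrownianMotion:
    def test_zero_rate_leaves_identical_to_root(self):
        tree = simulate_gene_tree(5, 1.0, seed=3)
        root = np.array([1.0, 2.0, 3.0])
        leaves = evolve_profiles(tree, 0.0, root, seed=4)
        for profile in leaves.values():
            assert np.allclose(profile, root)

    def test_variance_grows_linearly_with_path_length(self, rng):
        """Var(leaf - root) per stage ~ sigma^2 x root-to-leaf depth."""
        tree = simulate_gene_tree(4, 1.0, seed=9)
        label = tree.leaf_labels[0]
        # root-to-leaf depth: tree is ultrametric = half max patristic
        depth = phylo.patristic_distances(tree).values.max() / 2
        sigma2 = 0.7
        deviations = [evolve_profiles(tree, sigma2, np.zeros(2),
                                      seed=rng)[label][0]
                      for _ in range(2000)]
        observed = np.var(deviations)
        expected = sigma2 * depth
        assert observed == pytest.approx(expected, rel=0.15)

    def test_covariance_tracks_shared_path(self, rng):
        tree = phylo.parse_newick("((A:1,B:1):2,C:3);")
        sigma2 = 0.5
        a_vals, b_vals, c_vals = [], [], []
        for _ in range(2000):
            leaves = evolve_profiles(tree, sigma2, np.zeros(1), seed=rng)
            a_vals.append(leaves["A"][0])
            b_vals.append(leaves["B"][0])
            c_vals.append(leaves["C"][0])
        cov_ab = np.cov(a_vals, b_vals)[0, 1]
        cov_ac = np.cov(a_vals, c_vals)[0, 1]
        assert cov_ab == pytest.approx(sigma2 * 2.0, abs=0.15)
        assert cov_ac == pytest.approx(0.0, abs=0.15)


class TestHitsEmulation:
    def test_zero_distance_full_identity(self):
        tree = phylo.parse_newick("(A:0,B:0);")
        hits = make_hits({"G1": tree}, 0.2, None, {"A": 300, "B": 300})
        assert all(h.pident == pytest.approx(100.0) for h in hits)

    def test_pident_decreases_with_distance(self):
        tree = phylo.parse_newick("((A:0.1,B:0.1):1,C:2);")
        hits = {(h.query, h.target): h
                for h in make_hits({"G1": tree}, 0.2, None,
                                   {"A": 300, "B": 300, "C": 300})}
        assert hits[("A", "B")].pident > hits[("A", "C")].pident


class TestGenerateDataset:
    def test_matrix_dimensions_match_design(self, small_bundle):
        cfg = small_bundle.config
        expected_samples = (len(cfg.stages) * len(cfg.hosts)
                            * cfg.replicates_per_cell)
        n_dup = sum(len(g) for g in small_bundle.true_groups.values())
        assert small_bundle.expression.n_samples == expected_samples
        assert small_bundle.expression.n_genes == n_dup + cfg.n_singletons

    def test_all_tpm_non_negative(self, small_bundle):
        assert (small_bundle.expression.values.to_numpy() >= 0).all()

    def test_truth_patristic_consistent_with_emitted_newick(self,
                                                            small_bundle):
        trees = phylo.read_trees_dir(small_bundle.paths["trees"])
        truth = small_bundle.true_patristic
        for gid, sub in truth.groupby("group_id"):
            dm = phylo.patristic_distances(trees[gid]).to_dataframe()
            for _, row in sub.iterrows():
                assert dm.loc[row["gene_a"], row["gene_b"]] == pytest.approx(
                    row["distance"], abs=1e-9)

    def test_byte_identical_regeneration(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_groups=5, n_singletons=10)
        b1 = generate_dataset(cfg, tmp_path / "run1")
        b2 = generate_dataset(cfg, tmp_path / "run2")
        files1 = sorted(p.relative_to(b1.outdir)
                        for p in b1.outdir.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(b2.outdir)
                        for p in b2.outdir.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (b1.outdir / rel).read_bytes() == \
                (b2.outdir / rel).read_bytes(), rel

    def test_homology_recovers_true_partition(self, small_bundle):
        from stagediv.core_io import read_hits_tab
        hits = read_hits_tab(small_bundle.paths["hits"])
        thr = homology.PRESETS["lenient"]
        edges = homology.filter_hits(hits, thr.min_pident,
                                     thr.min_target_coverage, thr.max_evalue)
        gs = homology.build_groups(edges,
                                   small_bundle.expression.gene_ids)
        found = {frozenset(g) for g in gs.groups}
        expected = {frozenset(g)
                    for g in small_bundle.true_groups.values()}
        assert found == expected
        assert set(gs.singletons) == set(small_bundle.singletons)

    def test_null_boost_gives_similar_tau_distributions(self, tmp_path):
        """With no boost and no divergence, duplicate and singleton tau
        distributions are statistically indistinguishable."""
        from stagediv import preprocess
        from stagediv.specificity import build_tau_table
        cfg = SimulationConfig(seed=17, n_groups=20, n_singletons=60,
                               bm_rate=0.0, duplicate_specificity_boost=0.0,
                               root_profile_sd=0.0)
        bundle = generate_dataset(cfg, tmp_path / "null")
        logged = preprocess.log_transform(bundle.expression)
        medians = preprocess.stage_median_profiles(logged)
        # classify by ground truth rather than inferred homology
        dup = bundle.duplicate_genes
        taus = []
        from stagediv.specificity import tau
        for g, row in medians.values.iterrows():
            taus.append((g in dup, tau(row.to_numpy())))
        d = [t for is_dup, t in taus if is_dup]
        s = [t for is_dup, t in taus if not is_dup]
        assert ks_two_sample(d, s).p > 0.01
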