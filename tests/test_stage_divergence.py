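import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from stagediv.core_io import ExpressionMatrix, SampleMetadata
from stagediv.phylo import DistanceMatrix
from stagediv.stage_divergence import (adjacent_and_adult_pairs,
                                       manhattan_distances,
                                       pairwise_stage_tests,
                                       permanova_one_factor,
                                       permanova_two_factor)


def _dm_from_points(points):
    pts = np.asarray(points, dtype=float)
    labels = [f"s{i}" for i in range(len(pts))]
    return DistanceMatrix(labels, squareform(pdist(pts, "cityblock")))


def _matrix(values, stages, hosts=None, stage_order=None):
    hosts = hosts or ["h"] * len(stages)
    samples = [SampleMetadata(f"s{i}", st, ho, 1 + i)
               for i, (st, ho) in enumerate(zip(stages, hosts))]
    df = pd.DataFrame(np.asarray(values, dtype=float),
                      index=[f"g{i}" for i in range(len(values))],
                      columns=[s.sample_id for s in samples])
    order = stage_order or list(dict.fromkeys(stages))
    return ExpressionMatrix(df, samples, order)


class TestManhattan:
    def test_identical_samples_distance_zero(self):
        m = _matrix([[1, 1], [2, 2]], ["a", "b"])
        assert manhattan_distances(m).values[0, 1] == 0.0

    def test_hand_computed_l1(self):
        m = _matrix([[0, 1], [0, 2]], ["a", "b"])
        assert manhattan_distances(m).values[0, 1] == 3.0

    def test_triangle_inequality_on_random_triples(self, rng):
        m = _matrix(rng.uniform(0, 10, (20, 3)), ["a", "b", "c"])
        d = manhattan_distances(m).values
        for i, j, k in itertools.permutations(range(3), 3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-9


class TestOneFactorPermanova:
    def test_hand_computed_partition_and_F(self):
        dist = _dm_from_points([[0.0], [1.0], [10.0], [11.0]])
        table = permanova_one_factor(dist, ["A", "A", "B", "B"],
                                     n_permutations=99, seed=0)
        assert table.term("Total").ss == pytest.approx(101.0)
        assert table.term("Residual").ss == pytest.approx(1.0)
        assert table.term("factor").pseudo_f == pytest.approx(200.0)

    def test_r2_partition_sums_to_one(self, rng):
        pts = rng.uniform(0, 5, (9, 4))
        dist = _dm_from_points(pts)
        table = permanova_one_factor(dist, ["A"] * 3 + ["B"] * 3 + ["C"] * 3,
                                     n_permutations=99, seed=0)
        assert (table.term("factor").r2 + table.term("Residual").r2
                == pytest.approx(1.0, abs=1e-9))

    def test_F_invariant_under_sample_reordering(self, rng):
        pts = rng.uniform(0, 5, (8, 3))
        labels = ["A"] * 4 + ["B"] * 4
        dist = _dm_from_points(pts)
        f0 = permanova_one_factor(dist, labels, 99, seed=0).term(
            "factor").pseudo_f
        perm = rng.permutation(8)
        dist_p = DistanceMatrix([dist.labels[i] for i in perm],
                                dist.values[np.ix_(perm, perm)])
        f1 = permanova_one_factor(dist_p, [labels[i] for i in perm],
                                  99, seed=0).term("factor").pseudo_f
        assert f1 == pytest.approx(f0, abs=1e-9)

    def test_matches_exhaustive_permutation_oracle_n6(self, rng):
        """Monte-Carlo p agrees with the exact 720-relabeling null."""
        pts = rng.uniform(0, 4, (6, 2))
        labels = np.array(["A", "A", "A", "B", "B", "B"])
        dist = _dm_from_points(pts)
        d2 = dist.values ** 2
        n = 6

        def f_of(lbls):
            ss_total = d2[np.triu_indices(n, 1)].sum() / n
            ss_w = 0.0
            for lvl in ("A", "B"):
                idx = np.flatnonzero(lbls == lvl)
                ss_w += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
            k = 2
            return ((ss_total - ss_w) / (k - 1)) / (ss_w / (n - k))

        f_obs = f_of(labels)
        fs = [f_of(labels[list(p)])
              for p in itertools.permutations(range(n))]
        p_exact = np.mean([f >= f_obs - 1e-12 for f in fs])
        table = permanova_one_factor(dist, list(labels),
                                     n_permutations=999, seed=5)
        assert table.term("factor").pseudo_f == pytest.approx(f_obs)
        assert table.term("factor").p == pytest.approx(p_exact, abs=0.06)

    def test_matches_skbio_pseudo_f(self, rng):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        pts = rng.uniform(0, 4, (10, 3))
        labels = ["A"] * 5 + ["B"] * 5
        dist = _dm_from_points(pts)
        mine = permanova_one_factor(dist, labels, 99, seed=0)
        ref = skbio_dist.permanova(
            skbio_dist.DistanceMatrix(dist.values, dist.labels),
            grouping=labels, permutations=0)
        assert mine.term("factor").pseudo_f == pytest.approx(
            ref["test statistic"], abs=1e-9)

    def test_degenerate_within_gives_infinite_F(self):
        dist = _dm_from_points([[0.0], [0.0], [5.0], [5.0]])
        table = permanova_one_factor(dist, ["A", "A", "B", "B"], 99, seed=0)
        assert np.isinf(table.term("factor").pseudo_f)
        assert 0 < table.term("factor").p <= 1

    def test_more_groups_than_samples_rejected(self):
        dist = _dm_from_points([[0.0], [1.0], [2.0]])
        with pytest.raises(ValueError):
            permanova_one_factor(dist, ["A", "B", "C"], 99, seed=0)


class TestTwoFactorPermanova:
    # 8-sample 2x2 balanced toy; expected SS/F frozen from an independent
    # reference implementation of sequential-SS PERMANOVA.
    X = np.array([[0.1, 1.2], [0.4, 0.9], [2.1, 0.3], [1.7, 0.8],
                  [5.0, 4.2], [4.6, 5.5], [7.1, 6.0], [6.4, 6.9]])
    A = ["a1"] * 4 + ["a2"] * 4
    B = ["b1", "b1", "b2", "b2"] * 2

    def test_matches_frozen_reference_values(self):
        dist = _dm_from_points(self.X)
        table = permanova_two_factor(dist, self.A, self.B,
                                     n_permutations=999, seed=0)
        assert table.term("A").ss == pytest.approx(179.890, abs=1e-3)
        assert table.term("A").pseudo_f == pytest.approx(123.80592, abs=1e-4)
        assert table.term("A").r2 == pytest.approx(0.902722368586, abs=1e-9)
        assert table.term("B").ss == pytest.approx(12.120, abs=1e-3)
        assert table.term("B").pseudo_f == pytest.approx(8.34136, abs=1e-4)
        assert table.term("Residual").ss == pytest.approx(7.265, abs=1e-3)
        assert table.term("Total").ss == pytest.approx(199.275, abs=1e-3)

    def test_conservation_on_balanced_design(self):
        dist = _dm_from_points(self.X)
        table = permanova_two_factor(dist, self.A, self.B, n_permutations=99, seed=0)
        total = (table.term("A").ss + table.term("B").ss
                 + table.term("Residual").ss)
        assert total == pytest.approx(table.term("Total").ss, abs=1e-9)

    def test_constant_second_factor_reduces_to_one_factor(self):
        dist = _dm_from_points(self.X)
        one = permanova_one_factor(dist, self.A, 99, seed=0)
        with pytest.raises(ValueError, match="constant"):
            permanova_two_factor(dist, self.A, ["b"] * 8,
                                 n_permutations=99, seed=0)
        # term A of the additive model with a *non*-informative balanced B
        # still matches the one-factor SS
        table = permanova_two_factor(dist, self.A, self.B, n_permutations=99, seed=0)
        assert table.term("A").ss == pytest.approx(one.term("factor").ss,
                                                   abs=1e-9)


class TestPairwiseStages:
    @staticmethod
    def _stage_matrix(rng):
        stages = ["larva"] * 4 + ["pupa"] * 4 + ["adult"] * 4
        base = {"larva": 0.0, "pupa": 5.0, "adult": 9.0}
        vals = np.array([[base[s] + rng.normal(0, 0.3) for s in stages]
                         for _ in range(6)])
        return _matrix(np.abs(vals), stages,
                       stage_order=["larva", "pupa", "adult"])

    def test_duplicated_stage_centroid_distance_zero(self):
        m = _matrix([[1, 1, 2, 2], [3, 3, 4, 4]],
                    ["a", "a", "b", "b"], stage_order=["a", "b"])
        m2 = _matrix([[1, 1, 1, 1], [3, 3, 3, 3]],
                     ["a", "a", "b", "b"], stage_order=["a", "b"])
        res = pairwise_stage_tests(m2, [("a", "b")], 99, seed=0)[0]
        assert res.centroid_distance == pytest.approx(0.0)

    def test_hand_computed_centroid_l1(self):
        m = _matrix([[0, 0, 1, 1], [0, 0, 2, 2]],
                    ["a", "a", "b", "b"], stage_order=["a", "b"])
        res = pairwise_stage_tests(m, [("a", "b")], 99, seed=0)[0]
        assert res.centroid_distance == pytest.approx(3.0)

    def test_pair_order_symmetry(self, rng):
        m = self._stage_matrix(rng)
        r1 = pairwise_stage_tests(m, [("larva", "pupa")], 99, seed=4)[0]
        r2 = pairwise_stage_tests(m, [("pupa", "larva")], 99, seed=4)[0]
        assert r1.centroid_distance == pytest.approx(r2.centroid_distance)
        assert r1.pseudo_f == pytest.approx(r2.pseudo_f)

    def test_unknown_stage_rejected(self, rng):
        m = self._stage_matrix(rng)
        with pytest.raises(ValueError, match="imago"):
            pairwise_stage_tests(m, [("larva", "imago")], 99, seed=0)

    def test_default_pairs_adjacent_plus_larval_vs_adult(self):
        order = ["third_instar", "fifth_instar", "early_pupa",
                 "late_pupa", "adult"]
        pairs = adjacent_and_adult_pairs(order)
        assert ("third_instar", "fifth_instar") in pairs
        assert ("late_pupa", "adult") in pairs
        assert ("third_instar", "adult") in pairs
        assert ("fifth_instar", "adult") in pairs
        assert len(pairs) == 6
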