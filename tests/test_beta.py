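import numpy as np
import pandas as pd
import pytest

from forageome.beta import (clr_transform, dispersion_test,
                            euclidean_distances, pairwise_permanova, pca,
                            permanova)
from forageome.io import AsvTable, ValidationError
from forageome.simulate import simulate_null_pairs

from oracles import permanova_F_trace, permanova_exact_p


def _table(counts):
    counts = np.asarray(counts)
    return AsvTable([f"S{i}" for i in range(counts.shape[0])],
                    [f"A{i}" for i in range(counts.shape[1])], counts)


class TestClr:
    def test_identical_parts_map_to_zero(self):
        clr = clr_transform(_table([[1, 1, 1, 1], [7, 7, 7, 7]]))
        assert np.allclose(clr.values, 0.0)

    def test_rows_sum_to_zero(self, small_table):
        clr = clr_transform(small_table)
        assert np.allclose(clr.values.sum(axis=1), 0.0, atol=1e-9)

    def test_closed_form_e_fold_part(self):
        """A part e-fold larger than the three others lands at clr ≈ 0.75
        (= ln e − 1/4 after centring)."""
        k = 100000
        clr = clr_transform(_table([[int(round(np.e * k)) - 1, k - 1,
                                     k - 1, k - 1]]), pseudocount=1)
        assert clr.values[0, 0] == pytest.approx(0.75, abs=1e-4)
        assert clr.values[0, 1] == pytest.approx(-0.25, abs=1e-4)

    def test_depth_scale_invariance_small_pseudocount(self):
        x = np.array([[40, 10, 30, 20]])
        c1 = clr_transform(_table(x), pseudocount=1e-6)
        c2 = clr_transform(_table(3 * x), pseudocount=1e-6)
        assert np.allclose(c1.values, c2.values, atol=1e-5)

    def test_zero_total_asvs_dropped(self):
        clr = clr_transform(_table([[1, 0, 2], [3, 0, 4]]))
        assert clr.asv_ids == ["A0", "A2"]

    def test_matches_scikit_bio(self):
        from skbio.stats.composition import clr as skbio_clr
        x = np.array([[3, 9, 1, 5], [2, 2, 8, 4]])
        ours = clr_transform(_table(x), pseudocount=0.5)
        theirs = skbio_clr(x + 0.5)
        assert np.allclose(ours.values, theirs, atol=1e-12)


class TestPca:
    def test_two_samples_one_axis(self):
        clr = clr_transform(_table([[10, 1, 1], [1, 10, 1]]))
        res = pca(clr)
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_isometry_all_pcs(self, small_table):
        clr = clr_transform(small_table)
        res = pca(clr)
        from scipy.spatial.distance import pdist
        assert np.allclose(pdist(res.scores), pdist(clr.values), atol=1e-8)

    def test_sign_convention(self, small_table):
        clr = clr_transform(small_table)
        res = pca(clr, orient_negative=["S0", "S1"])
        assert res.scores[[0, 1], 0].mean() <= 0
        assert res.pc1_sign_fixed

    def test_constant_matrix_rejected(self):
        clr = clr_transform(_table([[5, 5], [5, 5], [5, 5]]))
        with pytest.raises(ValidationError, match="constant"):
            pca(clr)


class TestPermanova:
    def test_perfect_separation(self):
        D = np.ones((4, 4)) - np.eye(4)
        D[0, 1] = D[1, 0] = D[2, 3] = D[3, 2] = 0.0
        res = permanova(D, ["a", "a", "b", "b"], 99,
                        rng=np.random.default_rng(0))
        assert res.r_squared == pytest.approx(1.0)
        assert np.isinf(res.pseudo_F)

    def test_matches_trace_formula_oracle(self):
        t, labels = simulate_null_pairs(10, 40, seed=3)
        D = euclidean_distances(clr_transform(t)).to_numpy()
        res = permanova(D, labels["label"], 99, rng=np.random.default_rng(1))
        F_oracle, r2_oracle = permanova_F_trace(D, labels["label"].to_numpy())
        assert res.pseudo_F == pytest.approx(F_oracle, abs=1e-9)
        assert res.r_squared == pytest.approx(r2_oracle, abs=1e-9)

    def test_matches_scikit_bio(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova
        t, labels = simulate_null_pairs(12, 30, seed=9)
        D = euclidean_distances(clr_transform(t))
        ours = permanova(D, labels["label"], 99, rng=np.random.default_rng(2))
        theirs = skbio_permanova(DistanceMatrix(D.to_numpy(), ids=D.index),
                                 labels["label"].to_numpy(), permutations=99)
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"],
                                              abs=1e-9)

    def test_permutation_p_near_exact_enumeration(self):
        t, labels = simulate_null_pairs(8, 25, seed=17)
        D = euclidean_distances(clr_transform(t)).to_numpy()
        lab = labels["label"].to_numpy()
        p_exact = permanova_exact_p(D, lab)
        res = permanova(D, lab, 999, rng=np.random.default_rng(5))
        se = np.sqrt(p_exact * (1 - p_exact) / 999)
        assert abs(res.p_value - p_exact) <= 3 * se + 2 / 1000

    def test_reorder_invariance(self):
        t, labels = simulate_null_pairs(10, 30, seed=4)
        D = euclidean_distances(clr_transform(t)).to_numpy()
        lab = labels["label"].to_numpy()
        perm = np.random.default_rng(0).permutation(10)
        r1 = permanova(D, lab, 49, rng=np.random.default_rng(1))
        r2 = permanova(D[np.ix_(perm, perm)], lab[perm], 49,
                       rng=np.random.default_rng(1))
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F, abs=1e-9)

    def test_total_ss_conservation_with_clr_variance(self, small_table):
        """For Euclidean distances on CLR data, SS_total equals (n−1) times
        the total column variance of the CLR matrix."""
        clr = clr_transform(small_table)
        D = euclidean_distances(clr).to_numpy()
        n = D.shape[0]
        ss_total = (D ** 2).sum() / (2 * n)
        total_var = clr.values.var(axis=0, ddof=1).sum() * (n - 1)
        assert ss_total == pytest.approx(total_var, rel=1e-9)

    def test_p_value_bounds(self):
        t, labels = simulate_null_pairs(8, 20, seed=6)
        D = euclidean_distances(clr_transform(t))
        for s in range(3):
            res = permanova(D, labels["label"], 19,
                            rng=np.random.default_rng(s))
            assert 1 / 20 <= res.p_value <= 1.0

    def test_singleton_group_rejected(self):
        D = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValidationError, match="single sample"):
            permanova(D, ["a", "a", "b"], 9)


class TestPairwisePermanova:
    def test_identical_groups_not_significant(self):
        t, labels = simulate_null_pairs(18, 40, seed=11, n_groups=3)
        D = euclidean_distances(clr_transform(t))
        out = pairwise_permanova(D, labels["label"].to_numpy(), 99, seed=3)
        assert len(out) == 3
        assert (out["p_adjusted"] > 0.05).all()

    def test_pair_equals_direct_subset_run(self):
        t, labels = simulate_null_pairs(18, 40, seed=12, n_groups=3)
        D = euclidean_distances(clr_transform(t))
        lab = labels["label"].to_numpy()
        out = pairwise_permanova(D, lab, 99, seed=7)
        mask = np.isin(lab, ["marine", "switcher"])  # pair index 0 of sorted levels
        direct = permanova(D.to_numpy()[np.ix_(mask, mask)], lab[mask], 99,
                           rng=np.random.default_rng([7, 0]))
        row = out[out["term"] == "marine vs switcher"].iloc[0]
        assert row["F"] == pytest.approx(direct.pseudo_F, abs=1e-12)
        assert row["p"] == pytest.approx(direct.p_value, abs=1e-12)


class TestDispersion:
    def test_group_collapsed_at_centroid(self):
        X = np.vstack([np.zeros((3, 2)),
                       np.array([[1.0, 0], [3, 0], [2, 2]])])
        from scipy.spatial.distance import pdist, squareform
        D = squareform(pdist(X))
        res = dispersion_test(D, ["a"] * 3 + ["b"] * 3, 49,
                              rng=np.random.default_rng(0))
        means = res.group_means()
        assert means["a"] == pytest.approx(0.0, abs=1e-9)
        assert means["a"] < means["b"]

    def test_embedding_distances_match_direct_geometry(self):
        """For Euclidean distances the PCoA-embedding distances to group
        centroids must equal distances computed directly in CLR space."""
        t, labels = simulate_null_pairs(14, 30, seed=13)
        clr = clr_transform(t)
        D = euclidean_distances(clr)
        lab = labels["label"].to_numpy()
        ours = dispersion_test(D, lab, 49, rng=np.random.default_rng(1))
        X = clr.values
        z = np.empty(len(lab))
        for g in set(lab):
            m = lab == g
            c = X[m].mean(axis=0)
            z[m] = np.linalg.norm(X[m] - c, axis=1)
        got = ours.distances["distance_to_centroid"].to_numpy()
        assert np.allclose(got, z, atol=1e-10)

    def test_pairwise_table_one_row_per_pair(self):
        t, labels = simulate_null_pairs(18, 30, seed=14, n_groups=3)
        D = euclidean_distances(clr_transform(t))
        res = dispersion_test(D, labels["label"].to_numpy(), 49,
                              rng=np.random.default_rng(2))
        assert len(res.pairwise) == 3
        assert (res.pairwise["ci_low"] <= res.pairwise["ci_high"]).all()
        assert (res.pairwise["p_bonferroni"] >= res.pairwise["p_tukey"]).all()
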