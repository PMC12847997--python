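"""Distance matrices, Mantel, Procrustes, t-SNE."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from cohortseq import (
    CategoryLexicon,
    DistanceMatrix,
    category_distance_summary,
    classical_mds,
    difference_matrix,
    mantel_test,
    pairwise_distances,
    procrustes_align,
    tsne_embed,
)

from test_embed import manual_space


def random_dm(rng, n=6, dim=3, labels=None):
    pts = rng.normal(size=(n, dim))
    labels = labels or tuple(f"w{i}" for i in range(n))
    return DistanceMatrix(labels=tuple(labels), values=squareform(pdist(pts)),
                          metric="euclidean")


class TestDistanceMatrixType:
    def test_symmetry_enforced(self):
        vals = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(labels=("a", "b"), values=vals, metric="euclidean")

    def test_nonzero_diagonal_rejected(self):
        vals = np.array([[0.5, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(labels=("a", "b"), values=vals, metric="euclidean")


class TestPairwiseDistances:
    def test_three_four_five_triangles(self):
        sp = manual_space(["a", "b", "c"], [[0.0, 0.0], [3.0, 4.0], [6.0, 8.0]])
        dm = pairwise_distances(sp, ["a", "b", "c"], metric="euclidean")
        assert dm.values[0, 1] == pytest.approx(5.0)
        assert dm.values[1, 2] == pytest.approx(5.0)
        assert dm.values[0, 2] == pytest.approx(10.0)

    def test_identical_rows_zero_distance(self):
        sp = manual_space(["a", "b"], [[1.0, 2.0], [1.0, 2.0]])
        for metric in ("cosine", "euclidean"):
            dm = pairwise_distances(sp, ["a", "b"], metric=metric)
            assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_mahalanobis_identity_covariance_is_euclidean(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 3))
        sp = manual_space([f"w{i}" for i in range(8)], X)
        words = list(sp.vocabulary)
        dm_m = pairwise_distances(sp, words, metric="mahalanobis",
                                  covariance=np.eye(3))
        dm_e = pairwise_distances(sp, words, metric="euclidean")
        assert np.allclose(dm_m.values, dm_e.values)

    def test_euclidean_triangle_inequality_spot_check(self):
        rng = np.random.default_rng(1)
        sp = manual_space([f"w{i}" for i in range(10)], rng.normal(size=(10, 4)))
        dm = pairwise_distances(sp, list(sp.vocabulary), metric="euclidean")
        for i, j, k in itertools.permutations(range(10), 3):
            assert dm.values[i, j] <= dm.values[i, k] + dm.values[k, j] + 1e-9

    def test_unknown_metric(self):
        sp = manual_space(["a"], [[1.0, 0.0]])
        with pytest.raises(ValueError):
            pairwise_distances(sp, ["a"], metric="manhattan")


class TestCategorySummary:
    def test_tight_within_distinct_between(self):
        sp = manual_space(["a1", "a2", "b1", "b2"],
                          [[1, 0], [1, 0], [0, 5], [0, 5]])
        dm = pairwise_distances(sp, list(sp.vocabulary), metric="euclidean")
        lex = CategoryLexicon(categories={"A": ("a1", "a2"), "B": ("b1", "b2")})
        summ = category_distance_summary(dm, lex, space=sp)
        assert summ.loc["A", "within_mean"] == pytest.approx(0.0)
        assert summ.loc["A", "between_mean"] > 0
        assert summ.loc["A", "centroid_distance"] > 0

    def test_category_covering_all_labels_flagged(self):
        sp = manual_space(["a", "b"], [[1.0, 0.0], [0.0, 1.0]])
        dm = pairwise_distances(sp, ["a", "b"], metric="euclidean")
        lex = CategoryLexicon(categories={"ALL": ("a", "b")})
        summ = category_distance_summary(dm, lex)
        assert np.isnan(summ.loc["ALL", "between_mean"])

    def test_singleton_category_within_undefined(self):
        sp = manual_space(["a", "b"], [[1.0, 0.0], [0.0, 1.0]])
        dm = pairwise_distances(sp, ["a", "b"], metric="euclidean")
        lex = CategoryLexicon(categories={"S": ("a",), "T": ("b",)})
        summ = category_distance_summary(dm, lex)
        assert np.isnan(summ.loc["S", "within_mean"])

    def test_equidistant_points_within_equals_between(self):
        # 4 points, 2+2 split, all pairwise distances equal: enumerate 6 pairs
        vals = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(labels=("a1", "a2", "b1", "b2"), values=vals,
                            metric="cosine")
        lex = CategoryLexicon(categories={"A": ("a1", "a2"), "B": ("b1", "b2")})
        summ = category_distance_summary(dm, lex)
        assert summ.loc["A", "within_mean"] == pytest.approx(1.0)
        assert summ.loc["A", "between_mean"] == pytest.approx(1.0)


class TestDifferenceMatrix:
    def test_self_difference_zero(self):
        dm = random_dm(np.random.default_rng(0))
        assert np.allclose(difference_matrix(dm, dm), 0.0)

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(1)
        dm1, dm2 = random_dm(rng), random_dm(rng)
        assert np.allclose(difference_matrix(dm1, dm2),
                           -difference_matrix(dm2, dm1))

    def test_toy_values(self):
        d1 = DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]]), "euclidean")
        d2 = DistanceMatrix(("a", "b"), np.array([[0.0, 3.0], [3.0, 0.0]]), "euclidean")
        assert difference_matrix(d1, d2)[0, 1] == pytest.approx(-2.0)

    def test_label_alignment_and_mismatch(self):
        rng = np.random.default_rng(2)
        dm1 = random_dm(rng, labels=("a", "b", "c", "d", "e", "f"))
        perm = (2, 0, 1, 5, 4, 3)
        dm2 = DistanceMatrix(
            labels=tuple(dm1.labels[i] for i in perm),
            values=dm1.values[np.ix_(perm, perm)], metric="euclidean",
        )
        assert np.allclose(difference_matrix(dm1, dm2), 0.0)
        dm3 = random_dm(rng, labels=("a", "b", "c", "d", "e", "ZZZ"))
        with pytest.raises(ValueError, match="ZZZ"):
            difference_matrix(dm1, dm3)


def brute_force_mantel_p(dm1, dm2, method="pearson"):
    """Exhaustive permutation oracle for tiny matrices."""
    from scipy.stats import pearsonr, spearmanr

    iu = np.triu_indices(dm1.n, k=1)
    v2 = dm2.values[iu]

    def stat(v1):
        if method == "spearman":
            return spearmanr(v1, v2).statistic
        return pearsonr(v1, v2).statistic

    obs = stat(dm1.values[iu])
    n_ge = 0
    perms = list(itertools.permutations(range(dm1.n)))
    for perm in perms:
        if stat(dm1.values[np.ix_(perm, perm)][iu]) >= obs:
            n_ge += 1
    return n_ge / len(perms)


class TestMantel:
    def test_self_correlation_one(self):
        dm = random_dm(np.random.default_rng(3))
        res = mantel_test(dm, dm, n_permutations=99, seed=1)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_statistic_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import mantel as sk_mantel

        rng = np.random.default_rng(4)
        dm1, dm2 = random_dm(rng, n=8), random_dm(rng, n=8)
        for method in ("pearson", "spearman"):
            ours = mantel_test(dm1, dm2, method=method, n_permutations=10, seed=0)
            theirs, _, _ = sk_mantel(
                SkDM(dm1.values, ids=dm1.labels), SkDM(dm2.values, ids=dm2.labels),
                method=method, permutations=0,
            )
            assert ours.statistic == pytest.approx(theirs, abs=1e-12)

    def test_exhaustive_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(3):
            dm1, dm2 = random_dm(rng, n=4), random_dm(rng, n=4)
            res = mantel_test(dm1, dm2, exhaustive=True)
            assert res.p_value == pytest.approx(brute_force_mantel_p(dm1, dm2))
            assert res.n_permutations == 24

    def test_sampled_p_consistent_with_exhaustive(self):
        rng = np.random.default_rng(6)
        dm1, dm2 = random_dm(rng, n=5), random_dm(rng, n=5)
        exact = mantel_test(dm1, dm2, exhaustive=True).p_value
        sampled = mantel_test(dm1, dm2, n_permutations=4999, seed=7).p_value
        se = np.sqrt(exact * (1 - exact) / 4999)
        assert abs(sampled - exact) < 4 * se + 1e-3

    def test_constant_matrix_undefined(self):
        vals = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(("a", "b", "c", "d"), vals, "euclidean")
        with pytest.raises(ValueError, match="constant"):
            mantel_test(dm, dm, n_permutations=9)

    def test_p_in_unit_interval_convention(self):
        rng = np.random.default_rng(8)
        dm1, dm2 = random_dm(rng), random_dm(rng)
        res = mantel_test(dm1, dm2, n_permutations=99, seed=2)
        assert 0 < res.p_value <= 1
        assert res.p_value * 100 == int(res.p_value * 100)  # (1+k)/(1+n) grid


def rotation(theta):
    return np.array([[np.cos(theta), -np.sin(theta)],
                     [np.sin(theta), np.cos(theta)]])


class TestProcrustes:
    def test_transformed_copy_aligns_exactly(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(12, 2))
        Y = 3.1 * X @ rotation(1.2) + np.array([5.0, -2.0])
        res = procrustes_align(X, Y)
        assert res.ss == pytest.approx(0.0, abs=1e-12)
        assert res.correlation == pytest.approx(1.0)
        assert max(res.per_point_residuals.values()) < 1e-8

    def test_r_squared_identity(self):
        rng = np.random.default_rng(10)
        res = procrustes_align(rng.normal(size=(10, 3)), rng.normal(size=(10, 3)))
        assert res.correlation**2 == pytest.approx(1 - res.ss, abs=1e-12)

    def test_outlier_has_max_residual(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(10, 2))
        Y = X.copy()
        Y[4] += np.array([1.5, 1.5])
        labels = [f"w{i}" for i in range(10)]
        res = procrustes_align(X, Y, labels=labels)
        assert max(res.per_point_residuals, key=res.per_point_residuals.get) == "w4"

    def test_invariant_to_similarity_transforms(self):
        rng = np.random.default_rng(12)
        X, Y = rng.normal(size=(9, 2)), rng.normal(size=(9, 2))
        base = procrustes_align(X, Y).correlation
        X2 = 0.3 * X @ rotation(0.5) + 7.0
        Y2 = 12.0 * Y @ rotation(-2.0) - 3.0
        assert procrustes_align(X2, Y2).correlation == pytest.approx(base, abs=1e-10)

    def test_column_padding(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(8, 2))
        Y = np.column_stack([X, np.zeros(8)])
        assert procrustes_align(X, Y).correlation == pytest.approx(1.0)

    def test_protest_p_matches_independent_permutation_loop(self):
        """Permutation p against a loop built on scipy.spatial.procrustes."""
        from scipy.spatial import procrustes as scipy_procrustes

        rng = np.random.default_rng(14)
        X, Y = rng.normal(size=(10, 2)), rng.normal(size=(10, 2))
        res = procrustes_align(X, Y, n_permutations=999, seed=3)
        _, _, obs_disp = scipy_procrustes(X, Y)
        obs_corr = np.sqrt(1 - obs_disp)
        assert res.correlation == pytest.approx(obs_corr, abs=1e-10)
        rng2 = np.random.default_rng(99)
        n_ge = 0
        n_perm = 999
        for _ in range(n_perm):
            perm = rng2.permutation(10)
            _, _, disp = scipy_procrustes(X, Y[perm])
            if np.sqrt(1 - disp) >= obs_corr:
                n_ge += 1
        oracle_p = (1 + n_ge) / (1 + n_perm)
        se = np.sqrt(oracle_p * (1 - oracle_p) / n_perm)
        assert abs(res.permutation_p - oracle_p) < 4 * se + 5e-3

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            procrustes_align(np.zeros((2, 2)), np.zeros((2, 2)))

    def test_degenerate_configuration(self):
        with pytest.raises(ValueError, match="degenerate"):
            procrustes_align(np.ones((5, 2)), np.random.default_rng(0).normal(size=(5, 2)))


class TestClassicalMDS:
    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(15)
        pts = rng.normal(size=(7, 2))
        dm = DistanceMatrix(tuple(f"w{i}" for i in range(7)),
                            squareform(pdist(pts)), "euclidean")
        rec = classical_mds(dm, 2)
        assert procrustes_align(pts, rec).correlation == pytest.approx(1.0)


class TestTsne:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_separated_clusters_stay_separated(self, seed):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(seed)
        n_half = 40
        X = np.vstack([
            rng.normal(0, 1, size=(n_half, 15)),
            rng.normal(8, 1, size=(n_half, 15)),
        ])
        labels = [f"w{i}" for i in range(2 * n_half)]
        sp = manual_space(labels, X)
        tmap = tsne_embed(sp, labels, perplexity=20.0, seed=seed)
        groups = [0] * n_half + [1] * n_half
        assert silhouette_score(tmap.coordinates, groups) > 0.5
        assert np.isfinite(tmap.kl_divergence)

    def test_perplexity_infeasible(self):
        rng = np.random.default_rng(2)
        labels = [f"w{i}" for i in range(10)]
        sp = manual_space(labels, rng.normal(size=(10, 5)))
        with pytest.raises(ValueError, match="perplexity"):
            tsne_embed(sp, labels, perplexity=20.0)
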