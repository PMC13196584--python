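"""Distance-based multivariate statistics: hand oracles, enumeration
oracles, and cross-checks against independent implementations."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import magcsr as m
from magcsr.multivariate import DistLM, _gower_center, pcoa

from conftest import euclidean_dm


class TestSqrtBrayCurtis:
    def test_identical_samples_distance_zero(self):
        tbl = pd.DataFrame([[1, 2, 3], [2, 4, 6]], index=["a", "b"])
        dm = m.sqrt_bray_curtis(tbl)
        assert dm.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_distance_one(self):
        tbl = pd.DataFrame([[1, 0], [0, 5]], index=["a", "b"])
        dm = m.sqrt_bray_curtis(tbl)
        assert dm.data[0, 1] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # (0.25, 0.75) vs (1, 0): sqrt -> (0.5, 0.8660) vs (1, 0);
        # BC = (0.5 + 0.8660) / (1.5 + 0.8660) = 0.57735
        tbl = pd.DataFrame([[0.25, 0.75], [1.0, 0.0]], index=["a", "b"])
        dm = m.sqrt_bray_curtis(tbl)
        assert dm.data[0, 1] == pytest.approx(0.57735, abs=1e-4)

    def test_zero_total_sample_rejected_by_id(self):
        tbl = pd.DataFrame([[1, 1], [0, 0]], index=["ok", "void"])
        with pytest.raises(ValueError, match="void"):
            m.sqrt_bray_curtis(tbl)


class TestPcoa:
    def test_all_zero_distances(self):
        dm = m.DistanceMatrix(("a", "b", "c"), np.zeros((3, 3)))
        res = pcoa(dm)
        assert np.allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_collinear_points_recover_spacing(self):
        dm = euclidean_dm([0.0, 1.0, 2.0])
        res = pcoa(dm)
        axis1 = res.coordinates[:, 0]
        diffs = np.diff(np.sort(axis1))
        assert np.allclose(diffs, 1.0, atol=1e-8)
        assert np.allclose(res.eigenvalues[1:], 0.0, atol=1e-8)

    def test_eigenvalue_sum_equals_trace(self, rng):
        x = rng.gamma(1.0, size=(10, 6))
        dm = m.sqrt_bray_curtis(pd.DataFrame(x))
        res = pcoa(dm)
        g = _gower_center(dm.data)
        assert res.eigenvalues.sum() == pytest.approx(np.trace(g), abs=1e-8)

    def test_asymmetric_rejected(self):
        bad = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            m.DistanceMatrix(("a", "b"), bad)


class TestPermanova:
    def test_pseudo_f_matches_longhand_partition(self):
        # printed toy distance matrix, 2 groups of 3
        d = np.array([
            [0.0, 0.2, 0.3, 0.8, 0.9, 0.7],
            [0.2, 0.0, 0.25, 0.85, 0.8, 0.75],
            [0.3, 0.25, 0.0, 0.9, 0.85, 0.8],
            [0.8, 0.85, 0.9, 0.0, 0.15, 0.2],
            [0.9, 0.8, 0.85, 0.15, 0.0, 0.1],
            [0.7, 0.75, 0.8, 0.2, 0.1, 0.0],
        ])
        ids = tuple(f"s{i}" for i in range(6))
        dm = m.DistanceMatrix(ids, d)
        grp = pd.Series(["a"] * 3 + ["b"] * 3, index=ids)
        res = m.permanova(dm, grp, n_perm=99, seed=0)
        # long-hand sums of squares
        n, g = 6, 2
        ss_total = sum(d[i, j] ** 2 for i in range(6) for j in range(i + 1, 6)) / n
        ss_w = (sum(d[i, j] ** 2 for i in range(3) for j in range(i + 1, 3)) / 3
                + sum(d[i, j] ** 2 for i in range(3, 6)
                      for j in range(i + 1, 6)) / 3)
        f_hand = ((ss_total - ss_w) / (g - 1)) / (ss_w / (n - g))
        assert res.statistic == pytest.approx(f_hand, abs=1e-8)

    def test_monte_carlo_p_matches_enumeration(self):
        d = euclidean_dm([0.0, 0.1, 0.2, 5.0, 5.1, 5.2])
        ids = list(d.ids)
        grp = pd.Series(["a"] * 3 + ["b"] * 3, index=ids)
        res = m.permanova(d, grp, n_perm=9999, seed=3)
        # exact p over the 20 distinct two-group assignments
        codes = np.array([0, 0, 0, 1, 1, 1])
        from magcsr.multivariate import _permanova_f
        f_obs = _permanova_f(d.data**2, codes, 2)
        fs = []
        for subset in itertools.combinations(range(6), 3):
            c = np.ones(6, dtype=int)
            c[list(subset)] = 0
            fs.append(_permanova_f(d.data**2, c, 2))
        exact_p = np.mean([f >= f_obs - 1e-12 for f in fs])
        assert exact_p == pytest.approx(2 / 20)  # split and its mirror
        assert abs(res.p_value - exact_p) < 0.02

    def test_statistic_matches_reference_implementation(self, rng):
        import skbio
        x = rng.gamma(1.0, size=(15, 10))
        tbl = pd.DataFrame(x, index=[f"s{i}" for i in range(15)])
        dm = m.sqrt_bray_curtis(tbl)
        grp = pd.Series(["a"] * 5 + ["b"] * 5 + ["c"] * 5, index=list(dm.ids))
        res = m.permanova(dm, grp, n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.data, ids=list(dm.ids)),
            grp.values, permutations=99)
        assert res.statistic == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_singleton_group_rejected(self):
        d = euclidean_dm([0.0, 1.0, 2.0])
        grp = pd.Series(["a", "a", "b"], index=list(d.ids))
        with pytest.raises(ValueError, match="fewer than 2"):
            m.permanova(d, grp, n_perm=99)

    def test_calibrated_under_exchangeability(self, rng):
        # p approximately uniform: rejection rate at alpha=0.2 near 0.2
        rejections = 0
        n_runs = 100
        for i in range(n_runs):
            x = rng.normal(size=(12, 4))
            dm = euclidean_dm(x)
            grp = pd.Series(["a"] * 6 + ["b"] * 6, index=list(dm.ids))
            res = m.permanova(dm, grp, n_perm=99, seed=i)
            rejections += res.p_value <= 0.2
        rate = rejections / n_runs
        assert abs(rate - 0.2) < 3 * np.sqrt(0.2 * 0.8 / n_runs)


class TestPermdisp:
    def test_translated_clouds_have_equal_dispersion(self, rng):
        cloud = rng.normal(size=(8, 3))
        x = np.vstack([cloud, cloud + 50.0])
        dm = euclidean_dm(x)
        grp = pd.Series(["a"] * 8 + ["b"] * 8, index=list(dm.ids))
        res = m.permdisp(dm, grp, n_perm=999, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.9

    def test_f_matches_longhand_centroid_anova(self, rng):
        # Euclidean toy: centroid distances computable directly
        a = rng.normal(0, 1, size=(7, 2))
        b = rng.normal(0, 3, size=(9, 2))
        x = np.vstack([a, b])
        dm = euclidean_dm(x)
        grp = pd.Series(["a"] * 7 + ["b"] * 9, index=list(dm.ids))
        res = m.permdisp(dm, grp, n_perm=99, seed=0)
        za = np.linalg.norm(a - a.mean(axis=0), axis=1)
        zb = np.linalg.norm(b - b.mean(axis=0), axis=1)
        f_hand, _ = scipy.stats.f_oneway(za, zb)
        assert res.statistic == pytest.approx(f_hand, rel=1e-8)

    def test_statistic_matches_reference_on_metric_input(self, rng):
        import skbio
        x = rng.normal(size=(14, 3))
        dm = euclidean_dm(x)
        grp = pd.Series(["a"] * 7 + ["b"] * 7, index=list(dm.ids))
        res = m.permdisp(dm, grp, n_perm=99, seed=0)
        ref = skbio.stats.distance.permdisp(
            skbio.DistanceMatrix(dm.data, ids=list(dm.ids)),
            grp.values, permutations=99, test="centroid")
        assert res.statistic == pytest.approx(ref["test statistic"], rel=1e-6)


class TestCap:
    def test_separable_groups_reach_full_loo_success(self, rng):
        x = np.concatenate([rng.normal(0, 0.1, 10), rng.normal(10, 0.1, 10)])
        dm = euclidean_dm(x)
        grp = pd.Series(["a"] * 10 + ["b"] * 10, index=list(dm.ids))
        res = m.cap(dm, grp)
        assert res.loo_allocation_success == pytest.approx(1.0)
        assert res.m >= 1

    def test_single_group_rejected(self):
        dm = euclidean_dm([0.0, 1.0, 2.0])
        grp = pd.Series(["a"] * 3, index=list(dm.ids))
        with pytest.raises(ValueError, match="2 groups"):
            m.cap(dm, grp)

    def test_random_labels_near_chance(self, rng):
        x = rng.normal(size=(24, 5))
        dm = euclidean_dm(x)
        grp = pd.Series(rng.permutation(["a"] * 12 + ["b"] * 12),
                        index=list(dm.ids))
        res = m.cap(dm, grp, m=3)
        assert res.loo_allocation_success < 0.85  # chance is 0.5

    def test_invalid_m_rejected(self):
        dm = euclidean_dm([0.0, 1.0, 2.0, 3.0])
        grp = pd.Series(["a", "a", "b", "b"], index=list(dm.ids))
        with pytest.raises(ValueError, match="m must be"):
            m.cap(dm, grp, m=10)


class TestDistLM:
    def test_reduces_to_ols_under_euclidean_distance(self, rng):
        n = 30
        x = rng.normal(size=n)
        y = 1.5 * x + rng.normal(size=n)
        dm = euclidean_dm(y)
        preds = pd.DataFrame({"x": x}, index=list(dm.ids))
        res = DistLM(dm, preds).fit()
        r2_ols = scipy.stats.pearsonr(x, y)[0] ** 2
        _, r2, _ = DistLM(dm, preds).score(["x"])
        assert r2 == pytest.approx(r2_ols, abs=1e-8)
        assert res.r2 == pytest.approx(r2_ols, abs=1e-8)

    def test_duplicated_predictor_leaves_fit_unchanged(self, rng):
        n = 20
        x = rng.normal(size=n)
        y = x + rng.normal(size=n)
        dm = euclidean_dm(y)
        p1 = pd.DataFrame({"x": x}, index=list(dm.ids))
        p2 = pd.DataFrame({"x": x, "x_dup": x}, index=list(dm.ids))
        _, r2_single, _ = DistLM(dm, p1).score(["x"])
        _, r2_dup, _ = DistLM(dm, p2).score(["x", "x_dup"])
        assert r2_dup == pytest.approx(r2_single, abs=1e-8)

    def test_noise_predictor_marginal_r2_expectation(self, rng):
        # marginal R^2 of a predictor independent of the response has
        # expectation 1/(N-1) under Euclidean geometry
        n, n_rep = 20, 200
        r2s = []
        for _ in range(n_rep):
            y = rng.normal(size=n)
            x = rng.normal(size=n)
            dm = euclidean_dm(y)
            _, r2, _ = DistLM(dm, pd.DataFrame({"x": x}, index=list(dm.ids))
                              ).score(["x"])
            r2s.append(r2)
        mean = np.mean(r2s)
        sem = np.std(r2s) / np.sqrt(n_rep)
        assert abs(mean - 1 / (n - 1)) < 4 * sem

    def test_stepwise_trace_aicc_non_increasing(self, default_bundle):
        b = default_bundle
        rel = b.abundance.div(b.abundance.sum(axis=1), axis=0)
        frac = m.normalize_traits(b.trait_counts)
        cats = m.compute_cats(rel, frac)
        dm = m.sqrt_bray_curtis(b.abundance)
        res = DistLM(dm, cats).fit()
        aiccs = res.trace["aicc"].to_numpy()
        assert (np.diff(aiccs) < 0).all()
        assert set(res.selected) <= set(cats.columns)

    def test_sample_mismatch_rejected(self):
        dm = euclidean_dm([0.0, 1.0])
        preds = pd.DataFrame({"x": [1.0]}, index=["zzz"])
        with pytest.raises(ValueError, match="mismatch"):
            DistLM(dm, preds)


class TestDbrda:
    def test_single_binary_predictor_single_axis(self):
        y = np.array([0.0, 0.1, 0.2, 5.0, 5.1, 5.2])
        dm = euclidean_dm(y)
        preds = pd.DataFrame({"grp": [0, 0, 0, 1, 1, 1]}, index=list(dm.ids))
        res = m.dbrda(dm, preds)
        assert res.scores.shape[1] == 1
        assert res.percent_fitted[0] == pytest.approx(100.0)

    def test_percent_total_sums_to_model_r2(self, rng):
        x = rng.gamma(1.0, size=(15, 8))
        tbl = pd.DataFrame(x, index=[f"s{i}" for i in range(15)])
        dm = m.sqrt_bray_curtis(tbl)
        preds = pd.DataFrame(rng.normal(size=(15, 2)), index=list(dm.ids),
                             columns=["p1", "p2"])
        res = m.dbrda(dm, preds)
        _, r2, _ = DistLM(dm, preds).score(["p1", "p2"])
        assert res.percent_total.sum() / 100 == pytest.approx(r2, abs=1e-8)

    def test_orthogonal_effects_eigenvalue_ratio(self, rng):
        # two orthogonal binary contrasts with effect sizes 4 and 2 in a
        # Euclidean response: constrained eigenvalues scale as the
        # squared effect sizes (16:4)
        a = np.repeat([0, 1], 10)
        b = np.tile([0, 1], 10)
        y = np.column_stack([4.0 * a, 2.0 * b])
        dm = euclidean_dm(y)
        preds = pd.DataFrame({"a": a, "b": b}, index=list(dm.ids))
        res = m.dbrda(dm, preds)
        ratio = res.eigenvalues[0] / res.eigenvalues[1]
        assert ratio == pytest.approx(4.0, rel=1e-8)

    def test_empty_predictor_set_rejected(self):
        dm = euclidean_dm([0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="non-empty"):
            m.dbrda(dm, pd.DataFrame(index=list(dm.ids)))


class TestVectorOverlay:
    def test_variable_equal_to_axis_one(self, rng):
        scores = pd.DataFrame(rng.normal(size=(12, 2)),
                              columns=["ax1", "ax2"])
        scores -= scores.mean()
        scores["ax2"] -= (scores["ax2"] @ scores["ax1"]) / (
            scores["ax1"] @ scores["ax1"]) * scores["ax1"]  # orthogonalise
        variables = pd.DataFrame({"v": scores["ax1"]})
        out = m.vector_overlay(scores, variables, r_min=0.2)
        assert out.loc[0, "r_ax1"] == pytest.approx(1.0)
        assert out.loc[0, "r_ax2"] == pytest.approx(0.0, abs=1e-10)

    def test_constant_variable_excluded(self, rng):
        scores = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        out = m.vector_overlay(scores, pd.DataFrame({"c": np.ones(10)}),
                               r_min=0.0)
        assert out.empty

    def test_noisy_linear_variable_correlation(self, rng):
        n = 500
        scores = pd.DataFrame({"a1": rng.normal(size=n),
                               "a2": rng.normal(size=n)})
        beta = 0.6
        v = beta * scores["a1"] + rng.normal(size=n)
        expected_r = beta / np.sqrt(beta**2 + 1)
        out = m.vector_overlay(scores, pd.DataFrame({"v": v}), r_min=0.2)
        assert abs(out.loc[0, "r_a1"] - expected_r) < 0.1


class TestUpgmaClusters:
    def test_high_threshold_gives_singletons(self):
        dm = euclidean_dm([0.0, 0.5, 1.0])
        clusters = m.upgma_similarity_clusters(dm, similarity_threshold=99.9)
        assert clusters.nunique() == 3

    def test_low_threshold_gives_one_cluster(self):
        tbl = pd.DataFrame([[1, 2], [2, 1], [3, 1]], index=list("abc"))
        dm = m.sqrt_bray_curtis(tbl)
        clusters = m.upgma_similarity_clusters(dm, similarity_threshold=0.01)
        assert clusters.nunique() == 1

    def test_two_tight_pairs_split_at_85(self):
        # within-pair dissimilarity 0.05, between-pair 0.6; cutting at 85%
        # similarity (0.15 dissimilarity) yields exactly the two pairs
        d = np.array([
            [0.0, 0.05, 0.6, 0.6],
            [0.05, 0.0, 0.6, 0.6],
            [0.6, 0.6, 0.0, 0.05],
            [0.6, 0.6, 0.05, 0.0],
        ])
        dm = m.DistanceMatrix(("a", "b", "c", "d"), d)
        clusters = m.upgma_similarity_clusters(dm, similarity_threshold=85)
        assert clusters.nunique() == 2
        assert clusters["a"] == clusters["b"]
        assert clusters["c"] == clusters["d"]
        assert clusters["a"] != clusters["c"]
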