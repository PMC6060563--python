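import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from spinemorph.cluster import (MixtureModel, SpineGaussianMixture,
                                bhattacharyya_distance, bhattacharyya_matrix,
                                cluster_variance_summary, crosstab_chi2,
                                embed_mds, fit_mixture,
                                membership_threshold_table, memberships,
                                overlap_probability)


def two_component_2d(n=500, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal([0, 0], 1.0, (n // 2, 2))
    b = rng.normal([10, 10], 1.0, (n // 2, 2))
    return np.vstack([a, b])


class TestFit:
    def test_single_gaussian_selects_one_component(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (500, 2))
        model, bic = fit_mixture(X, range(1, 5), seed=0, n_init=2)
        assert model.n_components == 1

    def test_two_well_separated_gaussians_recovered(self):
        X = two_component_2d()
        model, bic = fit_mixture(X, range(1, 5), seed=0, n_init=2,
                                 standardize=False)
        assert model.n_components == 2
        means = model.means[np.argsort(model.means[:, 0])]
        np.testing.assert_allclose(means[0], [0, 0], atol=0.2)
        np.testing.assert_allclose(means[1], [10, 10], atol=0.2)

    def test_bic_curve_covers_requested_range(self):
        X = two_component_2d()
        _, bic = fit_mixture(X, range(2, 11), seed=0, n_init=1)
        assert len(bic) == 9
        assert list(bic.index) == list(range(2, 11))

    def test_bic_sign_convention_higher_is_better(self):
        X = two_component_2d()
        _, bic = fit_mixture(X, range(1, 4), seed=0, n_init=1,
                             standardize=False)
        assert bic.idxmax() == 2  # the true component count wins

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            fit_mixture(np.zeros((10, 2)), range(2, 11))

    def test_missing_values_rejected(self):
        X = two_component_2d()
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_mixture(X, range(1, 3))

    def test_sklearn_estimator_protocol(self):
        est = SpineGaussianMixture(c_min=1, c_max=3, n_init=1)
        params = est.get_params()
        assert params["c_min"] == 1
        est.set_params(c_max=2)
        X = two_component_2d()
        est.fit(X)
        assert est.predict(X).shape == (len(X),)
        assert est.predict_proba(X).shape == (len(X), est.n_components_)

    def test_em_log_likelihood_monotone(self):
        """EM never decreases the log-likelihood across iterations."""
        X = two_component_2d(seed=3)
        gmm = GaussianMixture(2, covariance_type="full", max_iter=1,
                              warm_start=True, init_params="k-means++",
                              random_state=0, tol=0.0, reg_covar=1e-6)
        lls = []
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(25):
                gmm.fit(X)
                lls.append(gmm.lower_bound_)
        assert all(b >= a - 1e-10 for a, b in zip(lls, lls[1:]))

    def test_label_permutation_leaves_bic_and_memberships_invariant(self):
        X = two_component_2d()
        model, bic = fit_mixture(X, [2], seed=0, n_init=2, standardize=False)
        perm = [1, 0]
        permuted = MixtureModel(weights=model.weights[perm],
                                means=model.means[perm],
                                covariances=model.covariances[perm],
                                log_likelihood=model.log_likelihood,
                                n_params=model.n_params)
        p0 = memberships(model, X).probabilities
        p1 = memberships(permuted, X).probabilities
        np.testing.assert_allclose(p0, p1[:, perm], atol=1e-12)


class TestMemberships:
    def model_1d(self, means=(0.0, 2.0), weights=(0.5, 0.5)):
        return MixtureModel(weights=list(weights),
                            means=[[m] for m in means],
                            covariances=np.array([[[1.0]], [[1.0]]]))

    def test_point_at_component_mean_dominates(self):
        m = MixtureModel(weights=[0.5, 0.5], means=[[0, 0], [20, 20]],
                         covariances=np.array([np.eye(2), np.eye(2)]))
        p = memberships(m, np.array([[0.0, 0.0]])).probabilities
        assert p[0, 0] > 0.999

    def test_symmetric_point_splits_evenly(self):
        p = memberships(self.model_1d(), np.array([[1.0]])).probabilities
        np.testing.assert_allclose(p, [[0.5, 0.5]], atol=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        p = memberships(self.model_1d(), rng.normal(1, 3, (200, 1)))
        np.testing.assert_allclose(p.probabilities.sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            memberships(self.model_1d(), np.zeros((5, 3)))

    def test_threshold_counts_nondecreasing_as_threshold_drops(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (300, 1)), rng.normal(2, 1, (300, 1))])
        mm = memberships(self.model_1d(), X)
        table = membership_threshold_table(mm)
        totals = table.sum(axis=1).to_numpy()
        assert np.all(np.diff(totals) >= 0)  # thresholds listed descending


class TestVarianceSummary:
    def mk(self, cov):
        cov = np.atleast_2d(cov)
        return MixtureModel(weights=[1.0], means=[np.zeros(len(cov))],
                            covariances=cov[None])

    def test_identity_gives_zero(self):
        assert cluster_variance_summary(self.mk(np.eye(4)))[0] == 0.0

    def test_diag_10_10_gives_two(self):
        out = cluster_variance_summary(self.mk(np.diag([10.0, 10.0])))
        assert abs(out[0] - 2.0) < 1e-12

    def test_matches_dense_determinant(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(5, 5))
        cov = A @ A.T + 5 * np.eye(5)
        out = cluster_variance_summary(self.mk(cov))[0]
        expected = abs(np.log10(np.linalg.det(cov)))
        assert abs(out - expected) / expected < 1e-8


class TestBhattacharyya:
    def test_identical_gaussians_zero(self):
        assert bhattacharyya_distance([1, 2], np.eye(2), [1, 2], np.eye(2)) == 0

    def test_mean_shift_closed_form(self):
        # equal unit variances: D = (1/8)(Δμ)² = 0.5 for Δμ = 2
        d = bhattacharyya_distance([0.0], [[1.0]], [2.0], [[1.0]])
        assert abs(d - 0.5) < 1e-12

    def test_variance_ratio_closed_form(self):
        # N(0,1) vs N(0,4): 0.5 ln(2.5/2) = 0.11157...
        d = bhattacharyya_distance([0.0], [[1.0]], [0.0], [[4.0]])
        assert abs(d - 0.5 * np.log(2.5 / 2.0)) < 1e-12

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_symmetric_and_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.integers(1, 5)
        ma, mb = rng.normal(size=d), rng.normal(size=d)
        A = rng.normal(size=(d, d))
        B = rng.normal(size=(d, d))
        ca = A @ A.T + np.eye(d)
        cb = B @ B.T + np.eye(d)
        ab = bhattacharyya_distance(ma, ca, mb, cb)
        ba = bhattacharyya_distance(mb, cb, ma, ca)
        assert abs(ab - ba) < 1e-9
        assert ab >= -1e-12

    def test_matrix_symmetric_zero_diagonal(self):
        m = MixtureModel(
            weights=[0.5, 0.3, 0.2],
            means=[[0, 0], [3, 0], [0, 4]],
            covariances=np.array([np.eye(2)] * 3),
        )
        D = bhattacharyya_matrix(m)
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0)
        assert np.all(D[~np.eye(3, dtype=bool)] > 0)


class TestMDS:
    def test_equilateral_triangle(self):
        D = np.ones((3, 3)) - np.eye(3)
        Y = embed_mds(D, dim=2)
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(Y), [1, 1, 1], atol=1e-8)

    def test_two_points(self):
        D = np.array([[0.0, 5.0], [5.0, 0.0]])
        Y = embed_mds(D, dim=2)
        assert abs(np.linalg.norm(Y[0] - Y[1]) - 5.0) < 1e-9

    def test_zero_matrix_collapses(self):
        Y = embed_mds(np.zeros((4, 4)), dim=2)
        assert np.allclose(Y, Y[0])

    def test_asymmetric_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            embed_mds(D)


class TestOverlap:
    def model(self, w=(0.5, 0.5)):
        return MixtureModel(weights=list(w), means=[[0.0], [2.0]],
                            covariances=np.array([[[1.0]], [[1.0]]]))

    def test_equal_priors_matches_phi(self):
        omega, se = overlap_probability(self.model(), 0, 1,
                                        n_samples=100_000, seed=0)
        assert abs(omega - (1 - norm.cdf(1.0))) < 0.01
        assert se <= 0.5 / np.sqrt(100_000) + 1e-12

    def test_unequal_priors_shifts_boundary(self):
        # boundary where 0.9 N(x|0,1) = 0.1 N(x|2,1): x = 1 + ln(9)/2
        omega, _ = overlap_probability(self.model((0.9, 0.1)), 0, 1,
                                       n_samples=100_000, seed=0)
        assert abs(omega - (1 - norm.cdf(1 + np.log(9) / 2))) < 0.01

    def test_separated_components_do_not_overlap(self):
        m = MixtureModel(weights=[0.5, 0.5], means=[[0.0], [20.0]],
                         covariances=np.array([[[1.0]], [[1.0]]]))
        omega, _ = overlap_probability(m, 0, 1, n_samples=100_000, seed=0)
        assert omega <= 0.001

    def test_asymmetry_tolerated(self):
        m = MixtureModel(weights=[0.5, 0.5], means=[[0.0], [1.0]],
                         covariances=np.array([[[1.0]], [[9.0]]]))
        a, _ = overlap_probability(m, 0, 1, n_samples=20_000, seed=1)
        b, _ = overlap_probability(m, 1, 0, n_samples=20_000, seed=1)
        assert 0 <= a <= 1 and 0 <= b <= 1
        assert abs(a - b) > 0.01  # ω is conditional, not symmetric

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            overlap_probability(self.model(), 0, 1, n_samples=50)


class TestCrosstab:
    def test_perfect_independence(self):
        labels = np.repeat([0, 1], 50)
        groups = np.tile([0, 1], 50)
        out = crosstab_chi2(labels, groups)
        assert out["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out["p_value"] == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # table [[10,20],[20,10]]: expected 15 everywhere, chi2 = 4*25/15 = 6.667
        labels = np.repeat([0, 1], 30)
        groups = np.concatenate([np.repeat([0, 1], [10, 20]),
                                 np.repeat([0, 1], [20, 10])])
        out = crosstab_chi2(labels, groups)
        assert out["statistic"] == pytest.approx(20 / 3, rel=1e-9)
        assert out["df"] == 1

    def test_per_cluster_mode_returns_one_test_each(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 3, 300)
        groups = rng.integers(0, 2, 300)
        out = crosstab_chi2(labels, groups, per_cluster=True)
        assert len(out) == 3
        for res in out.values():
            assert res["table"].shape == (2, 2)

    def test_single_category_rejected(self):
        with pytest.raises(ValueError):
            crosstab_chi2(np.zeros(10), np.tile([0, 1], 5))


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        m = MixtureModel(weights=[0.4, 0.6], means=[[0, 1], [2, 3]],
                         covariances=np.array([np.eye(2), 2 * np.eye(2)]),
                         feature_names=["a", "b"],
                         standardize_mean=np.array([1.0, 2.0]),
                         standardize_scale=np.array([3.0, 4.0]))
        p = tmp_path / "model.json"
        m.to_json(p)
        back = MixtureModel.from_json(p)
        np.testing.assert_allclose(back.means, m.means)
        np.testing.assert_allclose(back.covariances, m.covariances)
        np.testing.assert_allclose(back.standardize_scale, [3.0, 4.0])
        assert back.feature_names == ["a", "b"]
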