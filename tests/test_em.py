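import numpy as np
import pytest
from scipy.stats import multivariate_normal, ortho_group
from sklearn.decomposition import FactorAnalysis

from groupfa.em import (
    EStepResult,
    MFAParams,
    conditional_factor_mean,
    conditional_factor_second_moment,
    fit,
    group_density,
    hard_responsibilities,
    init_params,
    log_likelihood,
    m_step_loadings,
    m_step_psi,
    responsibilities,
)
from groupfa.preprocess import FeatureMatrix, GroupLabels
from groupfa.simulate import SyntheticSpec, generate

from conftest import random_params, small_cohort


def feature_matrix(values):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, d = values.shape
    return FeatureMatrix(values, [f"f{i}" for i in range(d)],
                         [f"s{i}" for i in range(n)])


class TestInitParams:
    def test_seeded_determinism(self, cohort):
        _, X, labels, _ = cohort
        a = init_params(X, labels, 2, seed=42)
        b = init_params(X, labels, 2, seed=42)
        np.testing.assert_array_equal(a.loadings, b.loadings)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.psi, b.psi)

    def test_group_means_recovered_exactly(self):
        X = feature_matrix([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        labels = GroupLabels([1, 1, 2, 2], ["a", "b"])
        p = init_params(X, labels, 1, seed=0)
        np.testing.assert_allclose(p.means, [[0, 0], [1, 1]])

    def test_psi_init_is_pooled_residual_variance(self):
        # standardized data, equal group means: pooled residual variance ~ 1
        rng = np.random.default_rng(5)
        vals = rng.standard_normal((4000, 3))
        vals = (vals - vals.mean(0)) / vals.std(0, ddof=1)
        X = feature_matrix(vals)
        labels = GroupLabels(rng.integers(1, 3, size=4000), ["a", "b"])
        p = init_params(X, labels, 1, seed=0)
        np.testing.assert_allclose(p.psi, np.ones(3), atol=0.01)

    def test_unreduced_model_rejected(self, cohort):
        _, X, labels, _ = cohort
        with pytest.raises(ValueError, match="not reduced"):
            init_params(X, labels, X.n_features, seed=0)


class TestGroupDensity:
    def test_standard_normal_at_origin(self):
        val = group_density(np.array([0.0]), np.array([[0.0]]),
                            np.array([0.0]), np.array([1.0]))
        assert val == pytest.approx(1 / np.sqrt(2 * np.pi), abs=1e-12)

    def test_integrates_to_one_univariate(self):
        grid = np.linspace(-10, 10, 20001)
        dens = [group_density(np.array([x]), np.array([[0.7]]),
                              np.array([0.3]), np.array([0.5])) for x in grid]
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-4)

    def test_two_dim_hand_value(self):
        # L = [1,1]^T, psi = I: cov = [[2,1],[1,2]], det = 3
        val = group_density(np.zeros(2), np.array([[1.0], [1.0]]),
                            np.zeros(2), np.ones(2))
        assert val == pytest.approx(1 / (2 * np.pi * np.sqrt(3)), rel=1e-12)

    def test_matches_scipy_on_random_instance(self, rng):
        L = rng.normal(size=(4, 2))
        mu = rng.normal(size=4)
        psi = rng.uniform(0.2, 1.0, 4)
        x = rng.normal(size=4)
        expected = multivariate_normal(mu, L @ L.T + np.diag(psi)).pdf(x)
        assert group_density(x, L, mu, psi) == pytest.approx(expected, rel=1e-10)


class TestResponsibilities:
    def test_single_group_always_one(self, rng):
        params = random_params(rng, m=1, d=4, k=2)
        X = feature_matrix(rng.normal(size=(6, 4)))
        np.testing.assert_allclose(responsibilities(X, params), 1.0)

    def test_identical_groups_split_evenly(self, rng):
        p1 = random_params(rng, m=1, d=3, k=1)
        params = MFAParams(
            np.repeat(p1.loadings, 2, axis=0),
            np.repeat(p1.means, 2, axis=0),
            p1.psi, np.array([0.5, 0.5]),
        )
        X = feature_matrix(rng.normal(size=(5, 3)))
        np.testing.assert_allclose(responsibilities(X, params), 0.5, atol=1e-12)

    def test_univariate_two_group_arithmetic(self):
        # mu = (-1, +1), unit variances, pi = (1/2, 1/2)
        params = MFAParams(np.zeros((2, 1, 1)), np.array([[-1.0], [1.0]]),
                           np.array([1.0]), np.array([0.5, 0.5]))
        h0 = responsibilities(feature_matrix([[0.0]]), params)
        np.testing.assert_allclose(h0, [[0.5, 0.5]], atol=1e-12)
        h1 = responsibilities(feature_matrix([[1.0]]), params)
        # density ratio exp(-2) / exp(0), normalized
        expected = np.exp(-2) / (np.exp(-2) + 1)
        assert h1[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_rows_sum_to_one(self, rng):
        params = random_params(rng, m=3, d=5, k=2)
        X = feature_matrix(rng.normal(size=(20, 5)))
        np.testing.assert_allclose(responsibilities(X, params).sum(axis=1), 1.0,
                                   atol=1e-10)


class TestHardResponsibilities:
    def test_diagnosis_indicator_pattern(self):
        labels = GroupLabels([1, 2, 3], ["NL", "vAD", "AD"])
        np.testing.assert_array_equal(hard_responsibilities(labels), np.eye(3))

    def test_single_group_all_ones(self):
        labels = GroupLabels([1, 1, 1, 1], ["only"])
        np.testing.assert_array_equal(hard_responsibilities(labels),
                                      np.ones((4, 1)))

    def test_permutation_equivariance(self, rng):
        labels = np.array([1, 2, 1, 2, 2, 1])
        perm = rng.permutation(6)
        a = hard_responsibilities(GroupLabels(labels, ["a", "b"]))[perm]
        b = hard_responsibilities(GroupLabels(labels[perm], ["a", "b"]))
        np.testing.assert_array_equal(a, b)


class TestConditionalMoments:
    def test_mean_zero_at_group_center(self, rng):
        L = rng.normal(size=(4, 2))
        mu = rng.normal(size=4)
        psi = rng.uniform(0.2, 1.0, 4)
        np.testing.assert_allclose(conditional_factor_mean(mu, L, mu, psi), 0.0)

    def test_zero_loading_gives_prior(self):
        L = np.zeros((3, 2))
        m = conditional_factor_mean(np.ones(3), L, np.zeros(3), np.ones(3))
        np.testing.assert_allclose(m, 0.0)
        s = conditional_factor_second_moment(np.zeros(3), L, np.zeros(3), np.ones(3))
        np.testing.assert_allclose(s, np.eye(2))

    def test_scalar_hand_example(self):
        # L = [1,1]^T, Psi = I, mu = 0, x = [1,1]: R = 3, E[f|x] = 2/3
        L = np.array([[1.0], [1.0]])
        m = conditional_factor_mean(np.ones(2), L, np.zeros(2), np.ones(2))
        assert m[0] == pytest.approx(2 / 3, rel=1e-12)
        s = conditional_factor_second_moment(np.ones(2), L, np.zeros(2), np.ones(2))
        assert s[0, 0] == pytest.approx(1 / 3 + (2 / 3) ** 2, rel=1e-12)

    def test_second_moment_minus_outer_mean_is_posterior_cov(self, rng):
        L = rng.normal(size=(5, 3))
        psi = rng.uniform(0.2, 1.0, 5)
        x = rng.normal(size=5)
        m = conditional_factor_mean(x, L, np.zeros(5), psi)
        s = conditional_factor_second_moment(x, L, np.zeros(5), psi)
        cov = s - np.outer(m, m)
        assert np.all(np.linalg.eigvalsh(cov) > 0)

    def test_woodbury_identity(self, rng):
        """(L^T Psi^-1 L + I)^-1 L^T Psi^-1 == L^T (L L^T + Psi)^-1."""
        for _ in range(20):
            L = rng.normal(size=(6, 3))
            psi = rng.uniform(0.1, 2.0, 6)
            x = rng.normal(size=6)
            lhs = conditional_factor_mean(x, L, np.zeros(6), psi)
            rhs = L.T @ np.linalg.solve(L @ L.T + np.diag(psi), x)
            np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestMStep:
    def test_weighted_mean_recovered_in_last_column(self, rng):
        # With K factors but zero conditional means, the last column of the
        # augmented loadings must be the responsibility-weighted mean.
        n, d, k = 12, 3, 2
        Xv = rng.normal(size=(n, d))
        X = feature_matrix(Xv)
        resp = rng.uniform(0.1, 1.0, size=(n, 2))
        resp /= resp.sum(axis=1, keepdims=True)
        estep = EStepResult(resp, np.zeros((n, 2, k)),
                            np.tile(np.eye(k), (n, 2, 1, 1)))
        L_aug = m_step_loadings(X, estep)
        for j in range(2):
            expected = (resp[:, j][:, None] * Xv).sum(0) / resp[:, j].sum()
            np.testing.assert_allclose(L_aug[j][:, -1], expected, atol=1e-10)

    def test_noiseless_regression_recovers_loadings(self, rng):
        # x_i = L f_i exactly, known scores substituted for the posterior
        n, d, k = 30, 4, 2
        L_true = rng.normal(size=(d, k))
        F = rng.normal(size=(n, k))
        X = feature_matrix(F @ L_true.T)
        aug_second = np.empty((n, 1, k, k))
        for i in range(n):
            aug_second[i, 0] = np.outer(F[i], F[i])
        estep = EStepResult(np.ones((n, 1)), F[:, None, :], aug_second)
        L_aug = m_step_loadings(X, estep)
        np.testing.assert_allclose(L_aug[0][:, :k], L_true, atol=1e-8)
        np.testing.assert_allclose(L_aug[0][:, -1], 0.0, atol=1e-8)

    def test_hard_labels_separate_group_support(self, rng):
        n, d, k = 20, 3, 1
        Xv = rng.normal(size=(n, d))
        labels = GroupLabels(np.repeat([1, 2], 10), ["a", "b"])
        resp = hard_responsibilities(labels)
        f_mean = rng.normal(size=(n, 2, k))
        f_second = np.tile(np.eye(k), (n, 2, 1, 1)) + \
            f_mean[:, :, :, None] * f_mean[:, :, None, :]
        estep = EStepResult(resp, f_mean, f_second)
        full = m_step_loadings(feature_matrix(Xv), estep)
        # perturbing the other group's rows leaves this group's solution alone
        Xv2 = Xv.copy()
        Xv2[10:] += 100.0
        again = m_step_loadings(feature_matrix(Xv2), estep)
        np.testing.assert_allclose(full[0], again[0], atol=1e-10)

    def test_psi_matches_bruteforce_summation(self, rng):
        n, d, k, m = 3, 2, 1, 2
        Xv = rng.normal(size=(n, d))
        resp = rng.uniform(0.1, 1, size=(n, m))
        resp /= resp.sum(1, keepdims=True)
        f_mean = rng.normal(size=(n, m, k))
        f_second = np.empty((n, m, k, k))
        for i in range(n):
            for j in range(m):
                f_second[i, j] = 0.5 + np.outer(f_mean[i, j], f_mean[i, j])
        estep = EStepResult(resp, f_mean, f_second)
        X = feature_matrix(Xv)
        L_aug = m_step_loadings(X, estep)
        psi, _ = m_step_psi(X, estep, L_aug, floor=1e-300)
        # independent plain-loop evaluation of the same update
        acc = np.zeros(d)
        for i in range(n):
            for j in range(m):
                ftil = np.append(f_mean[i, j], 1.0)
                resid = Xv[i] - L_aug[j] @ ftil
                acc += resp[i, j] * resid * Xv[i]
        np.testing.assert_allclose(psi, acc / n, atol=1e-12)

    def test_noiseless_exact_fit_floors_psi(self, rng):
        n, d, k = 40, 3, 1
        L_true = rng.normal(size=(d, k))
        F = rng.normal(size=(n, k))
        X = feature_matrix(F @ L_true.T)
        aug_second = F[:, None, :, None] * F[:, None, None, :]
        estep = EStepResult(np.ones((n, 1)), F[:, None, :], aug_second)
        L_aug = m_step_loadings(X, estep)
        psi, floored = m_step_psi(X, estep, L_aug, floor=1e-6)
        np.testing.assert_allclose(psi, 1e-6)
        assert floored == d

    def test_variance_reduction_single_group_no_factors(self, rng):
        # K = 0 limit emulated with zero loadings and mu = 0: the psi update
        # reduces to the diagonal of the sample second-moment matrix.
        n, d = 25, 3
        Xv = rng.normal(size=(n, d))
        estep = EStepResult(np.ones((n, 1)), np.zeros((n, 1, 1)),
                            np.zeros((n, 1, 1, 1)))
        L_aug = np.zeros((1, d, 2))  # zero loading and zero mean column
        psi, _ = m_step_psi(feature_matrix(Xv), estep, L_aug, floor=1e-300)
        np.testing.assert_allclose(psi, (Xv ** 2).mean(axis=0), atol=1e-12)


class TestLogLikelihood:
    def test_standard_normal_point(self):
        X = feature_matrix([[0.0]])
        params = MFAParams(np.zeros((1, 1, 1)), np.zeros((1, 1)),
                           np.ones(1), np.array([1.0]))
        labels = GroupLabels([1], ["g"])
        ll = log_likelihood(X, params, mode="supervised", labels=labels)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_soft_dominates_supervised(self, rng):
        params = random_params(rng, m=2, d=4, k=2)
        X = feature_matrix(rng.normal(size=(10, 4)))
        labels = GroupLabels(rng.integers(1, 3, size=10), ["a", "b"])
        soft = log_likelihood(X, params, mode="soft")
        sup = log_likelihood(X, params, mode="supervised", labels=labels)
        assert soft >= sup - 1e-10 + 10 * np.log(params.proportions.min())

    def test_matches_bruteforce_density_loop(self, rng):
        params = random_params(rng, m=2, d=2, k=1)
        Xv = rng.normal(size=(4, 2))
        X = feature_matrix(Xv)
        labels = GroupLabels([1, 2, 1, 2], ["a", "b"])
        expected_sup = sum(
            np.log(multivariate_normal(
                params.means[j], params.group_covariance(j)).pdf(Xv[i]))
            for i, j in enumerate(labels.labels - 1)
        )
        got = log_likelihood(X, params, mode="supervised", labels=labels)
        assert got == pytest.approx(expected_sup, abs=1e-10)
        expected_soft = sum(
            np.log(sum(
                params.proportions[j] * multivariate_normal(
                    params.means[j], params.group_covariance(j)).pdf(Xv[i])
                for j in range(2)))
            for i in range(4)
        )
        assert log_likelihood(X, params, mode="soft") == pytest.approx(
            expected_soft, abs=1e-10)

    def test_rotation_invariance(self, rng):
        """Replacing L_j by L_j H leaves the likelihood unchanged."""
        params = random_params(rng, m=2, d=6, k=3)
        X = feature_matrix(rng.normal(size=(15, 6)))
        labels = GroupLabels(rng.integers(1, 3, size=15), ["a", "b"])
        base = log_likelihood(X, params, mode="supervised", labels=labels)
        for _ in range(10):
            H = ortho_group.rvs(3, random_state=rng)
            rotated = MFAParams(
                np.stack([params.loadings[j] @ H for j in range(2)]),
                params.means, params.psi, params.proportions,
            )
            got = log_likelihood(X, rotated, mode="supervised", labels=labels)
            assert got == pytest.approx(base, abs=1e-8)


class TestFit:
    def test_single_iteration_contract(self, cohort):
        _, X, labels, _ = cohort
        res = fit(X, labels, 2, tol=np.inf, seed=0)
        assert res.n_iter == 1
        assert len(res.loglik_trace) == 2
        assert res.converged

    @pytest.mark.parametrize("mode", ["supervised", "soft"])
    def test_trace_nondecreasing_both_modes(self, mode):
        for seed in range(5):
            _, X, labels, _ = small_cohort(seed=seed, n=150, m=2, d=6, k=2)
            res = fit(X, labels, 2, mode=mode, max_iter=60, seed=seed)
            diffs = np.diff(res.loglik_trace)
            assert np.all(diffs >= -1e-8), f"seed {seed}: min diff {diffs.min()}"

    def test_single_group_matches_reference_factor_analysis(self):
        """With M=1 the model reduces to classical factor analysis."""
        rng = np.random.default_rng(11)
        d, k, n = 8, 2, 600
        params = random_params(rng, m=1, d=d, k=k)
        spec = SyntheticSpec(n, params, seed=11)
        X, labels, _ = generate(spec)
        res = fit(X, labels, k, tol=1e-12, max_iter=5000, seed=1)
        ours = res.params.group_covariance(0)
        ref = FactorAnalysis(n_components=k, tol=1e-10, max_iter=10000)
        ref.fit(X.values)
        theirs = ref.components_.T @ ref.components_ + np.diag(ref.noise_variance_)
        assert np.linalg.norm(ours - theirs) < 1e-3

    def test_degenerate_group_rejected(self):
        X = feature_matrix(np.random.default_rng(0).normal(size=(5, 3)))
        labels = GroupLabels([1, 1, 1, 1, 2], ["big", "tiny"])
        with pytest.raises(ValueError, match="tiny"):
            fit(X, labels, 1, seed=0)

    def test_supervised_recovery_loose(self):
        """Fitted covariance approaches truth as data grows."""
        _, X, labels, _ = small_cohort(seed=3, n=1500, m=2, d=6, k=2)
        spec, *_ = small_cohort(seed=3, n=1500, m=2, d=6, k=2)
        res = fit(X, labels, 2, seed=9, tol=1e-9)
        for j in range(2):
            truth = spec.true_params.group_covariance(j)
            got = res.params.group_covariance(j)
            rel = np.linalg.norm(got - truth) / np.linalg.norm(truth)
            assert rel < 0.25
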