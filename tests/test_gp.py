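"""GP regression surrogate: kernel, marginal-likelihood fit, posterior,
standardisation and partial-error additivity."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from cardiobo.gp import (
    Matern32GP,
    PartialErrorSurrogate,
    StandardisationMoments,
    destandardise_moments,
    matern32_ard,
    standardise,
)


class TestKernel:
    def test_diagonal_is_signal_variance(self, rng):
        X = rng.normal(size=(7, 3))
        K = matern32_ard(X, X, 2.5, [1.0, 0.5, 2.0])
        assert np.allclose(np.diag(K), 2.5)

    def test_symmetry(self, rng):
        X = rng.normal(size=(6, 2))
        K = matern32_ard(X, X, 1.3, [0.7, 1.4])
        assert np.allclose(K, K.T)

    def test_matches_direct_formula_on_grid(self, rng):
        """Grid-evaluation oracle: decreasing in each |dx|, -> 0 at infinity."""
        ls = np.array([0.8, 1.7])
        x0 = np.zeros((1, 2))
        for dim in range(2):
            deltas = np.linspace(0.1, 30, 50)
            X = np.zeros((50, 2))
            X[:, dim] = deltas
            k = matern32_ard(x0, X, 1.0, ls)[0]
            r = deltas / ls[dim]
            oracle = (1 + np.sqrt(3) * r) * np.exp(-np.sqrt(3) * r)
            assert np.allclose(k, oracle, atol=1e-12)
            assert np.all(np.diff(k) < 0)
        far = matern32_ard(x0, np.full((1, 2), 1e3), 1.0, ls)[0, 0]
        assert far < 1e-10

    def test_psd_after_jitter(self, rng):
        X = rng.uniform(size=(40, 3))
        K = matern32_ard(X, X, 1.0, [0.3, 0.3, 0.3]) + 1e-9 * np.eye(40)
        w = np.linalg.eigvalsh(K)
        assert w.min() > 0


def _dense_posterior_oracle(X, y, Xs, s2, sk2, ls, jitter):
    """Brute-force GP posterior with an explicit matrix inverse."""
    K = matern32_ard(X, X, sk2, ls) + (s2 + jitter) * np.eye(len(y))
    Ks = matern32_ard(Xs, X, sk2, ls)
    Kinv = np.linalg.inv(K)
    mean = Ks @ Kinv @ y
    var = sk2 - np.einsum("ij,jk,ik->i", Ks, Kinv, Ks)
    return mean, np.maximum(var, 0.0)


class TestPosterior:
    def test_matches_dense_oracle_on_random_sets(self, rng):
        for _ in range(20):
            n, d = 30, 3
            X = rng.uniform(size=(n, d))
            y = rng.normal(size=n)
            gp = Matern32GP(n_restarts=1, random_state=0)
            gp.fit(X, y)
            Xs = rng.uniform(size=(8, d))
            mean, std = gp.predict(Xs, return_std=True)
            om, ov = _dense_posterior_oracle(
                X, y, Xs, gp.noise_var_, gp.signal_var_, gp.length_scales_,
                gp.jitter_,
            )
            assert np.allclose(mean, om, atol=1e-8)
            assert np.allclose(std**2, ov, atol=1e-8)

    def test_interpolates_under_jitter_only_noise(self, rng):
        X = rng.uniform(size=(25, 2))
        y = np.sin(3 * X[:, 0]) + X[:, 1] ** 2
        gp = Matern32GP(n_restarts=2, noise_bounds=(1e-12, 1e-10), random_state=1)
        gp.fit(X, y)
        pred = gp.predict(X)
        assert np.max(np.abs(pred - y)) < 1e-6

    def test_prior_reversion_far_from_data(self, rng):
        X = rng.uniform(size=(15, 2))
        y = rng.normal(size=15)
        gp = Matern32GP(n_restarts=2, random_state=2)
        gp.fit(X, y)
        mean, std = gp.predict(np.full((1, 2), 1e4), return_std=True)
        assert abs(mean[0]) < 1e-6
        assert std[0] == pytest.approx(np.sqrt(gp.signal_var_), rel=1e-6)

    def test_matches_sklearn_reference(self, rng):
        """Independent cross-check against sklearn's GP with a Matern 1.5 kernel
        at identical, fixed hyperparameters."""
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import Matern

        n, d = 40, 2
        X = rng.uniform(size=(n, d))
        y = np.sin(4 * X[:, 0]) * np.cos(2 * X[:, 1])
        ls = np.array([0.4, 0.6])
        gp = Matern32GP(n_restarts=1, random_state=0)
        # bypass fitting: set hyperparameters directly and factorise
        gp.X_train_, gp.y_train_ = X, y
        gp.noise_var_, gp.signal_var_, gp.length_scales_ = 1e-8, 1.7, ls
        gp._refactor()
        sk = GaussianProcessRegressor(
            kernel=1.7 * Matern(length_scale=ls, nu=1.5),
            alpha=1e-8 + gp.jitter_,
            optimizer=None,
        ).fit(X, y)
        Xs = rng.uniform(size=(10, d))
        m1, s1 = gp.predict(Xs, return_std=True)
        m2, s2 = sk.predict(Xs, return_std=True)
        assert np.allclose(m1, m2, atol=1e-7)
        assert np.allclose(s1, s2, atol=1e-6)


class TestFit:
    def test_single_point_closed_form_lml(self):
        gp = Matern32GP(n_restarts=1, random_state=0)
        gp.fit(np.array([[0.5]]), np.array([0.7]))
        s2 = gp.noise_var_ + gp.signal_var_ + gp.jitter
        expected = -0.5 * (0.7**2 / s2 + np.log(2 * np.pi * s2))
        assert gp.log_marginal_likelihood_ == pytest.approx(expected, rel=1e-6)

    def test_deterministic_refit(self, rng):
        X = rng.uniform(size=(20, 2))
        y = rng.normal(size=20)
        g1 = Matern32GP(n_restarts=3, random_state=42).fit(X, y)
        g2 = Matern32GP(n_restarts=3, random_state=42).fit(X, y)
        assert np.array_equal(g1.length_scales_, g2.length_scales_)
        assert g1.log_marginal_likelihood_ == g2.log_marginal_likelihood_

    def test_length_scale_recovery_from_known_gp(self):
        """Median recovered length scales within factor 2 of truth (t=200, d=2)."""
        true_ls = np.array([0.3, 1.2])
        ratios = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.uniform(size=(200, 2))
            K = matern32_ard(X, X, 1.0, true_ls) + 1e-8 * np.eye(200)
            y = np.linalg.cholesky(K) @ rng.standard_normal(200)
            gp = Matern32GP(n_restarts=2, random_state=seed).fit(X, y)
            ratios.append(gp.length_scales_ / true_ls)
        med = np.median(np.array(ratios), axis=0)
        assert np.all(med > 0.5) and np.all(med < 2.0)

    def test_rank_one_update_matches_full_refactor(self, rng):
        X = rng.uniform(size=(20, 3))
        y = rng.normal(size=20)
        gp = Matern32GP(n_restarts=1, random_state=3).fit(X, y)
        xn, yn = rng.uniform(size=3), 0.3
        gp.add_point(xn, yn)
        ref = Matern32GP(n_restarts=1, random_state=3)
        ref.X_train_ = gp.X_train_
        ref.y_train_ = gp.y_train_
        ref.noise_var_, ref.signal_var_ = gp.noise_var_, gp.signal_var_
        ref.length_scales_ = gp.length_scales_
        ref._refactor()
        Xs = rng.uniform(size=(6, 3))
        m1, s1 = gp.predict(Xs, return_std=True)
        m2, s2 = ref.predict(Xs, return_std=True)
        assert np.allclose(m1, m2, atol=1e-9)
        assert np.allclose(s1, s2, atol=1e-9)


class TestStandardisation:
    def test_round_trip_identity(self, rng):
        Y = rng.normal(2.0, 3.0, size=(50, 4))
        m = StandardisationMoments.from_samples(Y)
        back = m.mean + m.sd * standardise(Y, m)
        assert np.allclose(back, Y, atol=1e-12)

    def test_constant_term_floor_collapses_variance(self):
        Y = np.full((30, 1), 5.0)
        m = StandardisationMoments.from_samples(Y)
        _, var = destandardise_moments(np.zeros(1), np.ones(1), m)
        assert var[0] < 1e-20

    def test_unit_moments_map_to_raw_moments(self):
        m = StandardisationMoments(mean=np.array([3.0]), sd=np.array([2.0]))
        mu, var = destandardise_moments(np.array([0.0]), np.array([1.0]), m)
        assert mu[0] == 3.0 and var[0] == 4.0


class TestPartialSurrogate:
    def _make(self, rng, n_terms=3, n=35):
        X = rng.uniform(size=(n, 2))
        parts = np.stack(
            [np.sin(3 * X[:, 0]) ** 2, X[:, 1] ** 2, 0.5 * (X * X).sum(axis=1)],
            axis=1,
        )[:, :n_terms]
        fac = lambda seed: Matern32GP(n_restarts=1, random_state=seed)
        ps = PartialErrorSurrogate(n_terms, gp_factory=fac, random_state=0)
        ps.fit(X, parts)
        return X, parts, ps

    def test_single_term_reduces_to_plain_gp(self, rng):
        X, parts, ps = self._make(rng, n_terms=1)
        gp = Matern32GP(n_restarts=1, random_state=0)
        yt = standardise(parts, ps.moments_)[:, 0]
        gp.fit(X, yt)
        Xs = rng.uniform(size=(5, 2))
        mu, var = ps.posterior(Xs)
        mt, st = gp.predict(Xs, return_std=True)
        mu_ref, var_ref = destandardise_moments(mt, st**2, StandardisationMoments(
            mean=ps.moments_.mean, sd=ps.moments_.sd))
        assert np.allclose(mu, mu_ref, atol=1e-10)
        assert np.allclose(var, var_ref, atol=1e-10)

    def test_total_moments_are_sums_of_partials_exactly(self, rng):
        X, parts, ps = self._make(rng)
        Xs = rng.uniform(size=(9, 2))
        mu, var = ps.posterior(Xs)
        mus, vars_ = ps.partial_posteriors(Xs)
        assert np.array_equal(mu, mus.sum(axis=0))
        assert np.array_equal(var, vars_.sum(axis=0))

    def test_additive_function_total_tracks_sum(self, rng):
        X, parts, ps = self._make(rng, n=60)
        Xs = rng.uniform(size=(40, 2))
        truth = (
            np.sin(3 * Xs[:, 0]) ** 2 + Xs[:, 1] ** 2 + 0.5 * (Xs * Xs).sum(axis=1)
        )
        mu, _ = ps.posterior(Xs)
        rmse = np.sqrt(np.mean((mu - truth) ** 2))
        assert rmse < 0.1 * truth.std()

    def test_shared_inputs_enforced(self, rng):
        _, _, ps = self._make(rng)
        assert all(
            np.array_equal(gp.X_train_, ps.X_train_) for gp in ps.gps_
        )

    def test_add_point_keeps_moments_frozen(self, rng):
        X, parts, ps = self._make(rng)
        m_before = ps.moments_
        ps.add_point(np.array([0.5, 0.5]), parts[0])
        assert ps.moments_ is m_before
        assert ps.X_train_.shape[0] == X.shape[0] + 1
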