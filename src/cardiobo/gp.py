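"""Gaussian-process regression surrogates with Matern 3/2 ARD kernels.

The surrogate for the (deterministic but expensive) objective is a zero-mean
GP with the Matern 3/2 kernel and automatic relevance determination,

    k(x, x') = sk2 * (1 + sqrt(3) r) * exp(-sqrt(3) r),
    r^2 = sum_i (x_i - x'_i)^2 / l_i^2,

plus an observation-noise variance s2 (a hyperparameter; the forward model is
deterministic, but a noise term absorbs numerical noise) and a small jitter
on the training covariance diagonal for factorisation stability.
Hyperparameters are chosen by maximising the log marginal likelihood
log N(y; 0, K + s2 I) with multi-start L-BFGS in log-hyperparameter space
(analytic gradients).

Two surrogate paradigms are supported downstream:

* a *target surrogate* -- one GP on the total objective;
* *partial error surrogates* -- one independent GP per squared-error term of
  the objective.  Since the terms are modelled as mutually independent, the
  posterior moments of the total are the sums of the per-term moments, and
  Expected Improvement stays in closed form.

Outputs are standardised per term with moments frozen on the initial design;
:class:`StandardisationMoments` records them and posterior moments are
de-standardised before use (mu = m0 + s0*mu_tilde, var = s0^2 * var_tilde).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.stats import qmc
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "matern32_ard",
    "Matern32GP",
    "GPFitError",
    "StandardisationMoments",
    "standardise",
    "destandardise_moments",
    "PartialErrorSurrogate",
]

_SQRT3 = np.sqrt(3.0)


class GPFitError(RuntimeError):
    """Kernel matrix could not be factorised even after jitter escalation."""


def matern32_ard(x, x2, signal_var: float, length_scales) -> np.ndarray:
    """Matern 3/2 ARD cross-covariance matrix between two point sets."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    X2 = np.atleast_2d(np.asarray(x2, dtype=float))
    ls = np.asarray(length_scales, dtype=float)
    d = X[:, None, :] / ls - X2[None, :, :] / ls
    r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    return signal_var * (1.0 + _SQRT3 * r) * np.exp(-_SQRT3 * r)


def _sq_dists_per_dim(X: np.ndarray) -> np.ndarray:
    """(n, n, d) array of per-dimension squared differences."""
    diff = X[:, None, :] - X[None, :, :]
    return diff**2


class Matern32GP(RegressorMixin, BaseEstimator):
    """Zero-mean GP regression with a Matern 3/2 ARD kernel.

    Parameters
    ----------
    n_restarts : multistart count for hyperparameter optimisation (Latin
        hypercube in log-space over the bounds; the current hyperparameters
        are included as an extra start when warm-started).
    jitter : diagonal stabiliser added to the training covariance; escalated
        multiplicatively (x10, up to ``max_jitter``) if factorisation fails.
    noise_bounds, signal_bounds, length_bounds : (low, high) bounds on the
        noise variance, signal variance and each ARD length scale.
    random_state : seed for the restart design.

    Fitted attributes: ``X_train_``, ``y_train_``, ``noise_var_``,
    ``signal_var_``, ``length_scales_``, ``log_marginal_likelihood_``.
    """

    def __init__(
        self,
        n_restarts: int = 8,
        jitter: float = 1e-9,
        max_jitter: float = 1e-4,
        noise_bounds: tuple[float, float] = (1e-10, 1.0),
        signal_bounds: tuple[float, float] = (1e-3, 1e3),
        length_bounds: tuple[float, float] = (0.03, 30.0),
        max_opt_iter: int = 60,
        random_state: int | None = None,
    ):
        self.n_restarts = n_restarts
        self.jitter = jitter
        self.max_jitter = max_jitter
        self.noise_bounds = noise_bounds
        self.signal_bounds = signal_bounds
        self.length_bounds = length_bounds
        self.max_opt_iter = max_opt_iter
        self.random_state = random_state

    # -- marginal likelihood -------------------------------------------------
    def _lml_and_grad(self, log_phi, X, y, D):
        n = len(y)
        s2, sk2 = np.exp(log_phi[0]), np.exp(log_phi[1])
        ls = np.exp(log_phi[2:])
        r2 = np.einsum("ijk,k->ij", D, 1.0 / ls**2)
        r = np.sqrt(np.maximum(r2, 0.0))
        E = np.exp(-_SQRT3 * r)
        K = sk2 * (1.0 + _SQRT3 * r) * E
        Ky = K + (s2 + self.jitter) * np.eye(n)
        try:
            L = np.linalg.cholesky(Ky)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros_like(log_phi)
        alpha = cho_solve((L, True), y)
        lml = (
            -0.5 * y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * n * np.log(2 * np.pi)
        )
        # dLML/dphi_j = 0.5 tr((aa^T - Ky^-1) dK/dphi_j)
        Kinv = cho_solve((L, True), np.eye(n))
        W = np.outer(alpha, alpha) - Kinv
        grad = np.empty_like(log_phi)
        grad[0] = 0.5 * np.trace(W) * s2
        grad[1] = 0.5 * np.sum(W * K)
        for i in range(len(ls)):
            dK = 3.0 * sk2 * E * (D[:, :, i] / ls[i] ** 2)
            grad[i + 2] = 0.5 * np.sum(W * dK)
        return -lml, -grad

    def _bounds_log(self, d):
        b = [self.noise_bounds, self.signal_bounds] + [self.length_bounds] * d
        return np.log(np.asarray(b))

    def fit(self, X, y, warm_start_hyper=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if len(y) < 1 or X.shape[0] != len(y):
            raise ValueError("need matching X, y with at least one point")
        n, d = X.shape
        D = _sq_dists_per_dim(X)
        lb = self._bounds_log(d)
        rng = np.random.default_rng(self.random_state)
        n_restarts = max(int(self.n_restarts), 1)
        sampler = qmc.LatinHypercube(
            d=d + 2, seed=rng.integers(2**31 - 1)
        )
        starts = lb[:, 0] + sampler.random(n_restarts) * (lb[:, 1] - lb[:, 0])
        start_list = list(starts)
        if warm_start_hyper is not None:
            start_list.insert(0, np.clip(warm_start_hyper, lb[:, 0], lb[:, 1]))
        best = None
        for x0 in start_list:
            res = minimize(
                self._lml_and_grad,
                x0,
                args=(X, y, D),
                jac=True,
                method="L-BFGS-B",
                bounds=lb,
                options={"maxiter": self.max_opt_iter},
            )
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise GPFitError("all hyperparameter starts failed")
        log_phi = best.x
        self.noise_var_ = float(np.exp(log_phi[0]))
        self.signal_var_ = float(np.exp(log_phi[1]))
        self.length_scales_ = np.exp(log_phi[2:])
        self.log_marginal_likelihood_ = float(-best.fun)
        self._log_phi_ = log_phi
        self.X_train_ = X
        self.y_train_ = y
        self._refactor()
        return self

    def _refactor(self):
        """(Re)build the Cholesky factor, escalating jitter if needed."""
        n = self.X_train_.shape[0]
        K = matern32_ard(
            self.X_train_, self.X_train_, self.signal_var_, self.length_scales_
        )
        jit = self.jitter
        while True:
            try:
                self._L_ = np.linalg.cholesky(K + (self.noise_var_ + jit) * np.eye(n))
                break
            except np.linalg.LinAlgError:
                jit *= 10.0
                if jit > self.max_jitter:
                    raise GPFitError(
                        f"covariance not positive definite at jitter {jit:g}"
                    ) from None
        self.jitter_ = jit
        self._alpha_ = cho_solve((self._L_, True), self.y_train_)

    def predict(self, X, return_std: bool = False):
        """Posterior mean (and latent standard deviation) at new inputs."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Ks = matern32_ard(X, self.X_train_, self.signal_var_, self.length_scales_)
        mean = Ks @ self._alpha_
        if not return_std:
            return mean
        V = solve_triangular(self._L_, Ks.T, lower=True)
        var = np.maximum(self.signal_var_ - np.einsum("ij,ij->j", V, V), 0.0)
        return mean, np.sqrt(var)

    # -- flat-text serialisation (for optimiser restart) --------------------
    def to_dict(self) -> dict:
        return {
            "kind": "matern32_gp",
            "X": self.X_train_.tolist(),
            "y": self.y_train_.tolist(),
            "noise_var": self.noise_var_,
            "signal_var": self.signal_var_,
            "length_scales": self.length_scales_.tolist(),
            "jitter": self.jitter,
            "params": self.get_params(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Matern32GP":
        gp = cls(**d["params"])
        gp.X_train_ = np.asarray(d["X"], dtype=float)
        gp.y_train_ = np.asarray(d["y"], dtype=float)
        gp.noise_var_ = float(d["noise_var"])
        gp.signal_var_ = float(d["signal_var"])
        gp.length_scales_ = np.asarray(d["length_scales"], dtype=float)
        gp._log_phi_ = np.log(
            np.concatenate([[gp.noise_var_, gp.signal_var_], gp.length_scales_])
        )
        gp._refactor()
        return gp

    def save(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "Matern32GP":
        import json

        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def add_point(self, x, y) -> "Matern32GP":
        """Rank-1 training-set extension without refitting hyperparameters."""
        x = np.asarray(x, dtype=float).reshape(1, -1)
        k = matern32_ard(x, self.X_train_, self.signal_var_, self.length_scales_)[0]
        kxx = self.signal_var_ + self.noise_var_ + self.jitter_
        l12 = solve_triangular(self._L_, k, lower=True)
        rest = kxx - l12 @ l12
        self.X_train_ = np.vstack([self.X_train_, x])
        self.y_train_ = np.append(self.y_train_, float(y))
        if rest <= 1e-12 * kxx:
            self._refactor()  # near-duplicate point; rebuild with safe jitter
            return self
        n = self.X_train_.shape[0]
        L = np.zeros((n, n))
        L[:-1, :-1] = self._L_
        L[-1, :-1] = l12
        L[-1, -1] = np.sqrt(rest)
        self._L_ = L
        self._alpha_ = cho_solve((self._L_, True), self.y_train_)
        return self


# ---------------------------------------------------------------------------
# Output standardisation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardisationMoments:
    """Per-term output mean and sd, frozen on the initial design.

    Degenerate (constant) terms get an sd floor so de-standardised variances
    collapse to ~0 instead of dividing by zero.
    """

    mean: np.ndarray
    sd: np.ndarray
    floor: float = 1e-12

    @staticmethod
    def from_samples(Y: np.ndarray, floor: float = 1e-12) -> "StandardisationMoments":
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        sd = Y.std(axis=0, ddof=0)
        return StandardisationMoments(
            mean=Y.mean(axis=0), sd=np.maximum(sd, floor), floor=floor
        )


def standardise(Y, moments: StandardisationMoments) -> np.ndarray:
    return (np.asarray(Y, dtype=float) - moments.mean) / moments.sd


def destandardise_moments(mu_tilde, var_tilde, moments: StandardisationMoments):
    """Map standardised posterior moments back to the original output scale."""
    mu = moments.mean + moments.sd * np.asarray(mu_tilde)
    var = moments.sd**2 * np.asarray(var_tilde)
    return mu, var


# ---------------------------------------------------------------------------
# Partial error surrogates
# ---------------------------------------------------------------------------

class PartialErrorSurrogate:
    """K* independent GPs over shared inputs, one per squared-error term.

    The total objective's posterior moments are the sums of the
    de-standardised per-term moments.  With ``n_terms=1`` this reduces to the
    plain target surrogate, so the optimiser treats both paradigms uniformly.
    """

    def __init__(
        self,
        n_terms: int,
        gp_factory=None,
        random_state: int | None = None,
    ):
        if n_terms < 1:
            raise ValueError("n_terms must be >= 1")
        self.n_terms = n_terms
        self.random_state = random_state
        if gp_factory is None:
            gp_factory = lambda seed: Matern32GP(random_state=seed)
        self._factory = gp_factory
        self.gps_: list[Matern32GP] | None = None
        self.moments_: StandardisationMoments | None = None

    def fit(self, X, Y_parts, moments: StandardisationMoments | None = None,
            warm_start: bool = False):
        """Fit all partial GPs on shared inputs X and (t, K*) outputs."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.atleast_2d(np.asarray(Y_parts, dtype=float))
        if Y.shape[1] != self.n_terms:
            raise ValueError(f"expected {self.n_terms} output columns")
        if moments is not None:
            self.moments_ = moments
        elif self.moments_ is None:
            self.moments_ = StandardisationMoments.from_samples(Y)
        Yt = standardise(Y, self.moments_)
        seed0 = self.random_state if self.random_state is not None else 0
        if self.gps_ is None or not warm_start:
            self.gps_ = [self._factory(seed0 + 1000 * i) for i in range(self.n_terms)]
            warm = [None] * self.n_terms
        else:
            warm = [gp._log_phi_ for gp in self.gps_]
        for i, gp in enumerate(self.gps_):
            gp.fit(X, Yt[:, i], warm_start_hyper=warm[i])
        return self

    def add_point(self, x, y_parts):
        yt = standardise(np.asarray(y_parts, dtype=float), self.moments_)
        for i, gp in enumerate(self.gps_):
            gp.add_point(x, yt[i])
        return self

    @property
    def X_train_(self) -> np.ndarray:
        return self.gps_[0].X_train_

    def posterior(self, X) -> tuple[np.ndarray, np.ndarray]:
        """De-standardised total posterior mean and variance at new inputs."""
        mu_tot = None
        var_tot = None
        for i, gp in enumerate(self.gps_):
            mt, st = gp.predict(X, return_std=True)
            m_i = StandardisationMoments(
                mean=self.moments_.mean[i : i + 1], sd=self.moments_.sd[i : i + 1]
            )
            mu, var = destandardise_moments(mt, st**2, m_i)
            mu_tot = mu if mu_tot is None else mu_tot + mu
            var_tot = var if var_tot is None else var_tot + var
        return mu_tot, var_tot

    def partial_posteriors(self, X):
        """Per-term de-standardised means and variances, shape (K*, m)."""
        mus, vars_ = [], []
        for i, gp in enumerate(self.gps_):
            mt, st = gp.predict(X, return_std=True)
            m_i = StandardisationMoments(
                mean=self.moments_.mean[i : i + 1], sd=self.moments_.sd[i : i + 1]
            )
            mu, var = destandardise_moments(mt, st**2, m_i)
            mus.append(mu)
            vars_.append(var)
        return np.array(mus), np.array(vars_)
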