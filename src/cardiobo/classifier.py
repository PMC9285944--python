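"""Probit GP classifier for simulator-crash (unknown-constraint) learning.

Forward solves can fail at parameter values that violate the model's
physiological assumptions.  Treating feasibility as an unknown constraint,
a GP classifier with a probit likelihood P(success | f) = Phi(y f) is trained
on the success/crash labels of all evaluated points, and the acquisition
function is weighted by the predicted success probability.

Inference uses expectation propagation (EP): each probit factor is replaced
by a local Gaussian "site" (nu_i, tau_i); sites are refined by cavity/moment
matching sweeps until convergence, with optional damping for stability.
The kernel is Matern 3/2 with ARD, matching the regression surrogate; kernel
hyperparameters are selected by maximising the EP approximation of the log
marginal likelihood over a small seeded candidate search.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from scipy.special import log_ndtr, ndtr
from scipy.stats import qmc

_LOG_INV_SQRT_2PI = -0.5 * np.log(2.0 * np.pi)
from sklearn.base import BaseEstimator, ClassifierMixin

from .gp import matern32_ard

__all__ = ["ProbitGPClassifier", "EPNonConvergenceError"]


class EPNonConvergenceError(RuntimeError):
    pass


def _log_phi_ratio(z):
    """log[ pdf(z) / cdf(z) ] evaluated stably for very negative z."""
    return _LOG_INV_SQRT_2PI - 0.5 * z * z - log_ndtr(z)


class ProbitGPClassifier(ClassifierMixin, BaseEstimator):
    """Binary GP classifier (labels +1/-1) with EP inference.

    Parameters: kernel signal variance / length-scale candidate bounds, EP
    sweep limits and damping.  ``fit`` runs EP at hyperparameters chosen by a
    seeded candidate search over the EP evidence; ``refresh_sites`` re-runs EP
    at the current hyperparameters (used every optimiser iteration, whereas
    full hyperparameter selection happens on a cadence).

    Fitted attributes: ``X_train_``, ``y_train_``, ``signal_var_``,
    ``length_scales_``, site parameters ``nu_tilde_``, ``tau_tilde_`` and the
    EP evidence ``log_evidence_``.
    """

    def __init__(
        self,
        signal_bounds: tuple[float, float] = (0.5, 50.0),
        length_bounds: tuple[float, float] = (0.05, 10.0),
        n_candidates: int = 8,
        max_sweeps: int = 40,
        tol: float = 1e-4,
        damping: float = 0.8,
        jitter: float = 1e-9,
        random_state: int | None = None,
    ):
        self.signal_bounds = signal_bounds
        self.length_bounds = length_bounds
        self.n_candidates = n_candidates
        self.max_sweeps = max_sweeps
        self.tol = tol
        self.damping = damping
        self.jitter = jitter
        self.random_state = random_state

    # -- EP core ------------------------------------------------------------
    def _ep(self, K, y, damping, init_sites=None, max_sweeps=None, strict=True):
        """One EP run; returns (nu~, tau~, chol, sqrt-sites, log evidence)."""
        n = len(y)
        if init_sites is None:
            nu_t = np.zeros(n)
            tau_t = np.zeros(n)
            Sigma = K.copy()
            mu = np.zeros(n)
        else:
            nu_t, tau_t = (np.asarray(a, dtype=float).copy() for a in init_sites)
            sr0 = np.sqrt(tau_t)
            B0 = np.eye(n) + sr0[:, None] * K * sr0[None, :]
            L0 = np.linalg.cholesky(B0)
            V0 = solve_triangular(L0, sr0[:, None] * K, lower=True)
            Sigma = K - V0.T @ V0
            mu = Sigma @ nu_t
        if max_sweeps is None:
            max_sweeps = self.max_sweeps
        for _ in range(max_sweeps):
            max_delta = 0.0
            for i in range(n):
                sii = Sigma[i, i]
                tau_cav = 1.0 / sii - tau_t[i]
                nu_cav = mu[i] / sii - nu_t[i]
                if tau_cav <= 0:
                    continue  # skip unstable cavity; damped sweeps recover
                m_cav, v_cav = nu_cav / tau_cav, 1.0 / tau_cav
                z = y[i] * m_cav / np.sqrt(1.0 + v_cav)
                ratio = np.exp(_log_phi_ratio(z))
                dm = y[i] * ratio / np.sqrt(1.0 + v_cav)
                dv = -ratio * (z + ratio) / (1.0 + v_cav)
                m_hat = m_cav + v_cav * dm
                v_hat = v_cav + v_cav**2 * dv
                v_hat = max(v_hat, 1e-12)
                tau_new = 1.0 / v_hat - tau_cav
                nu_new = m_hat / v_hat - nu_cav
                tau_new = max(tau_new, 1e-12)
                d_tau = damping * (tau_new - tau_t[i])
                d_nu = damping * (nu_new - nu_t[i])
                max_delta = max(max_delta, abs(d_tau), abs(d_nu))
                tau_t[i] += d_tau
                nu_t[i] += d_nu
                # rank-1 posterior update
                si = Sigma[:, i]
                denom = 1.0 + d_tau * sii
                Sigma = Sigma - np.outer(si, si) * (d_tau / denom)
                mu = Sigma @ nu_t
            if max_delta < self.tol:
                break
        else:
            if strict:
                raise EPNonConvergenceError("EP did not converge")
        # recompute posterior from scratch for numerical hygiene
        sr = np.sqrt(tau_t)
        B = np.eye(n) + sr[:, None] * K * sr[None, :]
        L = np.linalg.cholesky(B)
        log_ev = self._log_evidence(K, y, nu_t, tau_t, L, sr)
        return nu_t, tau_t, L, sr, log_ev

    def _log_evidence(self, K, y, nu_t, tau_t, L, sr):
        """EP approximate log marginal likelihood (Rasmussen-Williams 3.65 form)."""
        n = len(y)
        V = solve_triangular(L, sr[:, None] * K, lower=True)
        Sigma = K - V.T @ V
        mu = Sigma @ nu_t
        diagS = np.diag(Sigma)
        tau_cav = 1.0 / np.maximum(diagS, 1e-12) - tau_t
        nu_cav = mu / np.maximum(diagS, 1e-12) - nu_t
        tau_cav = np.maximum(tau_cav, 1e-12)
        m_cav = nu_cav / tau_cav
        z = y * m_cav / np.sqrt(1.0 + 1.0 / tau_cav)
        lZ = np.sum(log_ndtr(z))
        lZ += 0.5 * np.sum(np.log1p(tau_t / tau_cav)) - np.sum(np.log(np.diag(L)))
        t_sum = tau_cav + tau_t
        lZ += 0.5 * nu_t @ (Sigma - np.diag(1.0 / t_sum)) @ nu_t
        lZ += 0.5 * m_cav @ np.diag(tau_cav) @ (
            np.diag(tau_t / t_sum) @ m_cav - 2 * np.diag(1.0 / t_sum) @ nu_t
        )
        return float(lZ)

    def _run_ep(self, K, y):
        try:
            return self._ep(K, y, self.damping)
        except EPNonConvergenceError:
            return self._ep(K, y, 0.3 * self.damping)

    # -- sklearn-style API ----------------------------------------------------
    def fit(self, X, y):
        """Select hyperparameters by EP-evidence candidate search, then run EP."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if not np.all(np.isin(y, (-1.0, 1.0))):
            raise ValueError("labels must be +/-1")
        if len(np.unique(y)) < 2:
            raise ValueError(
                "need both classes; use the trivial always-feasible model until "
                "the first crash is observed"
            )
        d = X.shape[1]
        rng = np.random.default_rng(self.random_state)
        lb = np.log(np.asarray([self.signal_bounds] + [self.length_bounds] * d))
        sampler = qmc.LatinHypercube(d=d + 1, seed=rng.integers(2**31 - 1))
        cands = np.exp(lb[:, 0] + sampler.random(self.n_candidates) * (lb[:, 1] - lb[:, 0]))
        cands = np.vstack([[np.sqrt(np.prod(self.signal_bounds))]
                           + [np.sqrt(np.prod(self.length_bounds))] * d, cands])
        if hasattr(self, "signal_var_"):  # warm start from the current setting
            cands = np.vstack([[self.signal_var_, *self.length_scales_], cands])
        best = None
        for c in cands:
            K = matern32_ard(X, X, c[0], c[1:]) + self.jitter * np.eye(len(y))
            try:
                out = self._run_ep(K, y)
            except (EPNonConvergenceError, np.linalg.LinAlgError):
                continue
            if best is None or out[-1] > best[1][-1]:
                best = (c, out)
        if best is None:
            raise EPNonConvergenceError("EP failed for all hyperparameter candidates")
        c, (nu_t, tau_t, L, sr, log_ev) = best
        self.X_train_ = X
        self.y_train_ = y
        self.signal_var_ = float(c[0])
        self.length_scales_ = np.asarray(c[1:], dtype=float)
        self.nu_tilde_, self.tau_tilde_ = nu_t, tau_t
        self._L_, self._sr_ = L, sr
        self.log_evidence_ = log_ev
        self._finalise()
        return self

    def refresh_sites(self, X, y, warm: bool = False, max_sweeps: int | None = None):
        """Re-run EP on (possibly grown) data at the current hyperparameters.

        With ``warm=True`` the stored site parameters (zero-padded for new
        points) seed EP and a short non-strict sweep budget is used -- the
        incremental per-iteration update; the periodic full refit cleans up.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        K = matern32_ard(X, X, self.signal_var_, self.length_scales_)
        K += self.jitter * np.eye(len(y))
        if warm and hasattr(self, "nu_tilde_"):
            pad = len(y) - len(self.nu_tilde_)
            init = (
                np.append(self.nu_tilde_, np.zeros(pad)),
                np.append(self.tau_tilde_, np.zeros(pad)),
            )
            nu_t, tau_t, L, sr, log_ev = self._ep(
                K, y, self.damping, init_sites=init,
                max_sweeps=max_sweeps or 5, strict=False,
            )
        else:
            nu_t, tau_t, L, sr, log_ev = self._run_ep(K, y)
        self.X_train_, self.y_train_ = X, y
        self.nu_tilde_, self.tau_tilde_ = nu_t, tau_t
        self._L_, self._sr_ = L, sr
        self.log_evidence_ = log_ev
        self._finalise()
        return self

    def _finalise(self):
        K = matern32_ard(
            self.X_train_, self.X_train_, self.signal_var_, self.length_scales_
        ) + self.jitter * np.eye(len(self.y_train_))
        sr = self._sr_
        # z = S^1/2 B^-1 S^1/2 K nu~  (predictive mean weights)
        rhs = sr * (K @ self.nu_tilde_)
        tmp = cho_solve((self._L_, True), rhs)
        self._wmean_ = self.nu_tilde_ - sr * tmp

    def latent(self, X):
        """Posterior latent mean and variance at new inputs."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Ks = matern32_ard(X, self.X_train_, self.signal_var_, self.length_scales_)
        mu = Ks @ self._wmean_
        V = solve_triangular(self._L_, self._sr_[:, None] * Ks.T, lower=True)
        var = np.maximum(self.signal_var_ - np.einsum("ij,ij->j", V, V), 1e-12)
        return mu, var

    def predict_proba(self, X) -> np.ndarray:
        """P(success) (the +1 class) at new inputs, in [0, 1]."""
        mu, var = self.latent(X)
        return ndtr(mu / np.sqrt(1.0 + var))

    def predict(self, X) -> np.ndarray:
        return np.where(self.predict_proba(X) >= 0.5, 1.0, -1.0)

    # -- flat-text serialisation (for optimiser restart) --------------------
    def to_dict(self) -> dict:
        return {
            "kind": "probit_gp_classifier",
            "X": self.X_train_.tolist(),
            "y": self.y_train_.tolist(),
            "signal_var": self.signal_var_,
            "length_scales": self.length_scales_.tolist(),
            "nu_tilde": self.nu_tilde_.tolist(),
            "tau_tilde": self.tau_tilde_.tolist(),
            "params": self.get_params(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProbitGPClassifier":
        clf = cls(**d["params"])
        clf.X_train_ = np.asarray(d["X"], dtype=float)
        clf.y_train_ = np.asarray(d["y"], dtype=float)
        clf.signal_var_ = float(d["signal_var"])
        clf.length_scales_ = np.asarray(d["length_scales"], dtype=float)
        clf.nu_tilde_ = np.asarray(d["nu_tilde"], dtype=float)
        clf.tau_tilde_ = np.asarray(d["tau_tilde"], dtype=float)
        n = len(clf.y_train_)
        K = matern32_ard(clf.X_train_, clf.X_train_, clf.signal_var_,
                         clf.length_scales_) + clf.jitter * np.eye(n)
        sr = np.sqrt(clf.tau_tilde_)
        B = np.eye(n) + sr[:, None] * K * sr[None, :]
        clf._L_ = np.linalg.cholesky(B)
        clf._sr_ = sr
        clf.log_evidence_ = clf._log_evidence(
            K, clf.y_train_, clf.nu_tilde_, clf.tau_tilde_, clf._L_, sr
        )
        clf._finalise()
        return clf

    def save(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "ProbitGPClassifier":
        import json

        with open(path) as fh:
            return cls.from_dict(json.load(fh))
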