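"""Expected Improvement acquisition, crash-constraint weighting, and the
inner (acquisition-surface) global maximisation.

For a minimisation problem with incumbent f* and GP posterior N(mu, s^2) at a
candidate, the Expected Improvement E[max(f* - y, 0)] has the closed form

    EI = (f* - mu) Phi(z) + s phi(z),    z = (f* - mu) / s,

degenerating to max(f* - mu, 0) as s -> 0.  With unknown feasibility
constraints (simulator crashes) EI is weighted by the classifier's success
probability: EIcon = EI * P(x feasible).

The inner maximisation uses a seeded multistart scheme: a Latin-hypercube
scan of the box, local derivative-free refinement of the best starts and of
a scatter-search-style reference set of good known solutions, and
deduplication of converged optima.  (Commercial scatter-search global
optimisers are often used for this step; this documented multistart plays
that role and the optimiser is pluggable through this module's single
entry point.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr
from scipy.stats import qmc

_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)

__all__ = [
    "expected_improvement",
    "constrained_ei",
    "AcquisitionEval",
    "maximise_acquisition",
]


def expected_improvement(mu, s, f_star: float):
    """Closed-form EI for minimisation; array-friendly; s >= 0."""
    mu = np.asarray(mu, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("predictive standard deviation must be non-negative")
    imp = f_star - mu
    with np.errstate(divide="ignore", invalid="ignore", over="ignore",
                     under="ignore"):
        z = np.where(s > 0, imp / np.where(s > 0, s, 1.0), 0.0)
        phi = _INV_SQRT_2PI * np.exp(-0.5 * z * z)
        ei = np.where(s > 0, imp * ndtr(z) + s * phi, np.maximum(imp, 0.0))
    return np.maximum(ei, 0.0)


@dataclass(frozen=True)
class AcquisitionEval:
    """EI, feasibility probability and their product at one candidate."""

    x: np.ndarray
    ei: float
    p_success: float

    @property
    def ei_con(self) -> float:
        return self.ei * self.p_success


def constrained_ei(x, posterior, classifier, f_star: float) -> AcquisitionEval:
    """EIcon = EI(x) * P(success at x).

    ``posterior`` maps points to (mean, variance); ``classifier`` exposes
    ``predict_proba`` or is None (no crash observed yet -> P = 1).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    mu, var = posterior(x)
    ei = float(expected_improvement(mu, np.sqrt(np.maximum(var, 0.0)), f_star)[0])
    p = 1.0 if classifier is None else float(classifier.predict_proba(x)[0])
    return AcquisitionEval(x=x[0], ei=ei, p_success=min(max(p, 0.0), 1.0))


def maximise_acquisition(
    acq,
    bounds,
    n_starts: int = 64,
    n_refine: int = 10,
    refine_maxfev: int = 60,
    seed: int | None = None,
    variance_fn=None,
    dedup_tol: float = 1e-4,
    extra_starts=None,
):
    """Global maximisation of an acquisition surface over a box.

    ``acq`` maps an (m, d) array to (m,) acquisition values.  Strategy:
    Latin-hypercube scan with ``n_starts`` points (plus box centre and any
    ``extra_starts``, e.g. the incumbent's location, which seeds the
    exploitation peak that a space-filling scan rarely hits), local
    Nelder-Mead refinement of the ``n_refine`` best scan points and of every
    extra start, deduplication of converged optima within ``dedup_tol``
    (ties broken towards the lowest lexicographic coordinate), best returned.  If the whole surface is
    numerically zero the point of highest ``variance_fn`` (if given) among
    the scan is returned as a pure-exploration fallback.
    """
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    if not np.all(np.isfinite(bounds)) or np.any(hi <= lo):
        raise ValueError("bounds must be finite with lower < upper")
    d = len(lo)
    rng = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=d, seed=rng.integers(2**31 - 1))
    Xs = lo + sampler.random(n_starts) * (hi - lo)
    Xs = np.vstack([Xs, 0.5 * (lo + hi)])
    n_extra = 0
    if extra_starts is not None and len(extra_starts) > 0:
        extra = np.clip(np.atleast_2d(np.asarray(extra_starts, dtype=float)), lo, hi)
        n_extra = len(extra)
        Xs = np.vstack([Xs, extra])
    vals = np.asarray(acq(Xs), dtype=float)

    if not np.any(vals > 0.0):
        if variance_fn is not None:
            var = np.asarray(variance_fn(Xs), dtype=float)
            return Xs[int(np.argmax(var))].copy()
        return Xs[int(np.argmax(vals))].copy()

    n_scan = len(Xs) - n_extra
    order = np.argsort(vals[:n_scan])[::-1][: max(n_refine, 1)]
    order = np.concatenate([order, np.arange(n_scan, len(Xs))])
    optima: list[tuple[np.ndarray, float]] = []
    neg = lambda x: -float(acq(np.clip(x, lo, hi)[None, :])[0])
    for idx in order:
        res = minimize(
            neg,
            Xs[idx],
            method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={"maxfev": refine_maxfev, "xatol": 1e-6, "fatol": 1e-12},
        )
        x_opt = np.clip(res.x, lo, hi)
        f_opt = -res.fun
        merged = False
        for j, (xo, fo) in enumerate(optima):
            if np.max(np.abs(xo - x_opt)) < dedup_tol:
                # keep the better value; tie -> lexicographically smallest point
                if f_opt > fo or (f_opt == fo and tuple(x_opt) < tuple(xo)):
                    optima[j] = (x_opt, f_opt)
                merged = True
                break
        if not merged:
            optima.append((x_opt, f_opt))
    best = max(optima, key=lambda t: (t[1], tuple(-c for c in t[0])))
    return best[0].copy()
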