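"""Pre-trained GP emulator of the 30 mmHg cavity volume.

Evaluating the Klotz-penalised objective needs the simulated volume at
30 mmHg as well as 8 mmHg, doubling the forward-solve cost and exposing the
run to high-pressure crashes.  Instead, a GP emulator of V30 is trained once,
ahead of optimisation, on a space-filling design over the material scalings
theta and a single geometry summary statistic -- the load-free volume proxy
V0hat -- so one emulator serves a range of LV geometries.

The training design varies geometry by uniform (shape-preserving) scaling of
the reference geometry to hit target load-free volumes; crashed design points
are excluded.  Queries far outside the training hull raise a warning flag.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.stats import qmc
from sklearn.base import BaseEstimator, RegressorMixin

from .constitutive import as_theta
from .forward import CylindricalLVModel, GeometrySpec
from .gp import Matern32GP, StandardisationMoments, destandardise_moments, standardise

__all__ = ["V30Emulator", "generate_v30_design", "scale_geometry_to_v0"]


def scale_geometry_to_v0(base: GeometrySpec, v0_target_ml: float) -> GeometrySpec:
    """Uniformly rescale a geometry so its load-free cavity volume matches.

    Shape-preserving scaling (radius, wall and length together) keeps the
    pressure-stretch response invariant, so volumes scale exactly with the
    target; it is the simplest one-parameter family of LV sizes for the
    emulator's geometry axis.
    """
    s = float((v0_target_ml / base.reference_volume_ml) ** (1.0 / 3.0))
    return replace(
        base,
        r_inner=base.r_inner * s,
        wall_thickness=tuple(t * s for t in base.wall_thicknesses),
        length=base.length * s,
        torsion_rate=base.torsion_rate / s,
        label=f"{base.label}-v0scaled",
    )


def generate_v30_design(
    base_geom: GeometrySpec,
    box,
    v0_range_ml: tuple[float, float],
    n_points: int,
    ref="in_vivo_gao",
    seed: int | None = None,
):
    """LHS design over (theta, V0hat) with simulated V30 outputs.

    Returns (X, y): X columns are theta1..theta4 and V0hat (mL); y is the
    simulated 30 mmHg volume (mL).  Crashed points are dropped.
    """
    box = np.asarray(box, dtype=float)
    lo = np.append(box[:, 0], v0_range_ml[0])
    hi = np.append(box[:, 1], v0_range_ml[1])
    sampler = qmc.LatinHypercube(d=5, seed=seed)
    U = lo + sampler.random(n_points) * (hi - lo)
    X, y = [], []
    for row in U:
        geom = scale_geometry_to_v0(base_geom, row[4])
        res = CylindricalLVModel(geom).inflate(row[:4], ref, 30.0)
        if not res.crashed:
            X.append(row)
            y.append(res.volume_ml)
    return np.asarray(X), np.asarray(y)


class V30Emulator(RegressorMixin, BaseEstimator):
    """GP regression emulator V30(theta, V0hat), volumes in mL."""

    def __init__(
        self,
        n_restarts: int = 4,
        hull_margin: float = 0.1,
        random_state: int | None = None,
    ):
        self.n_restarts = n_restarts
        self.hull_margin = hull_margin
        self.random_state = random_state

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[1] != 5:
            raise ValueError("inputs must be (theta1..theta4, V0hat)")
        if np.any(y <= 0):
            raise ValueError("V30 training outputs must be positive")
        self.lo_ = X.min(axis=0)
        self.hi_ = X.max(axis=0)
        self.range_ = np.maximum(self.hi_ - self.lo_, 1e-12)
        self.moments_ = StandardisationMoments.from_samples(y[:, None])
        self.gp_ = Matern32GP(
            n_restarts=self.n_restarts,
            noise_bounds=(1e-10, 1e-2),
            random_state=self.random_state,
        )
        yt = (y - self.moments_.mean[0]) / self.moments_.sd[0]
        self.gp_.fit((X - self.lo_) / self.range_, yt)
        return self

    def outside_hull(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        U = (X - self.lo_) / self.range_
        return np.any((U < -self.hull_margin) | (U > 1.0 + self.hull_margin), axis=1)

    def predict(self, X, return_flag: bool = False):
        """Predicted V30 (mL); optionally a far-outside-training-hull flag."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        mt = self.gp_.predict((X - self.lo_) / self.range_)
        mu, _ = destandardise_moments(mt, np.zeros_like(mt), self.moments_)
        mu = np.asarray(mu).ravel()
        if return_flag:
            return mu, self.outside_hull(X)
        return mu

    def predict_single(self, theta, v0hat_ml: float) -> float:
        x = np.append(as_theta(theta), v0hat_ml)
        return float(self.predict(x[None, :])[0])
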