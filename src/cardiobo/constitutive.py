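"""Holzapfel-Ogden constitutive law for passive myocardium.

The myocardium is modelled as an incompressible, invariant-based hyperelastic
material with a layered fibre architecture: an isotropic matrix term, two
fibre-family terms (myocyte direction ``f0`` and sheet direction ``s0``) and a
fibre-sheet shear coupling term.  The strain energy density is

    W = a/(2b)  * exp[b (I1 - 3)]
      + sum_{i in {f, s}} a_i/(2 b_i) * ( exp[b_i <I4i - 1>^2] - 1 )
      + afs/(2 bfs) * ( exp[bfs I8fs^2] - 1 ),

where ``<x> = max(x, 0)`` implements the standard tension-only convention for
the anisotropic terms (collagen fibres do not stiffen in compression), and the
invariants of the right Cauchy-Green tensor C = F^T F are

    I1 = tr C,  I4f = f0 . C f0,  I4s = s0 . C s0,  I8fs = f0 . C s0.

The eight constitutive parameters (a, b, af, bf, as, bs, afs, bfs) are
collected in :class:`ConstitutiveParams`.  ``a``-type parameters carry units
of kPa, ``b``-type parameters are dimensionless exponents.

Because the eight parameters are strongly correlated and not identifiable from
sparse in vivo data, inference operates on a reduced four-dimensional
parametrisation: positive scalings theta = (t1, t2, t3, t4) of a literature
reference vector, applied group-wise (matrix / fibre+sheet stiffness /
fibre+sheet exponents / shear), see :func:`descale`.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "ConstitutiveParams",
    "DeformationState",
    "InvariantSet",
    "StressState",
    "REFERENCE_VECTORS",
    "reference_vector",
    "as_theta",
    "descale",
    "invariants",
    "strain_energy",
    "cauchy_stress",
    "uniaxial_curve",
]

#: Pressure unit conversion used at all external interfaces.
KPA_PER_MMHG = 0.133322


class InvalidParameterError(ValueError):
    """A constitutive parameter or scaling violated positivity."""


class IncompressibilityError(ValueError):
    """A deformation gradient was not unimodular within tolerance."""


class ConfigurationError(ValueError):
    """Inconsistent traction-free conditions for the Lagrange multiplier."""


@dataclass(frozen=True)
class ConstitutiveParams:
    """The eight Holzapfel-Ogden parameters; a-types in kPa, b-types unitless."""

    a: float
    b: float
    af: float
    bf: float
    as_: float
    bs: float
    afs: float
    bfs: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0.0:
                raise InvalidParameterError(
                    f"constitutive parameter {f.name!r} must be strictly "
                    f"positive and finite, got {v!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.a, self.b, self.af, self.bf, self.as_, self.bs, self.afs, self.bfs]
        )

    @staticmethod
    def from_array(x: np.ndarray) -> "ConstitutiveParams":
        a, b, af, bf, as_, bs, afs, bfs = np.asarray(x, dtype=float)
        return ConstitutiveParams(a, b, af, bf, as_, bs, afs, bfs)


#: Literature reference vectors.  ``ex_vivo_wang`` was fitted to ex vivo simple
#: shear data; ``in_vivo_gao`` is an in vivo population-wide average.
REFERENCE_VECTORS: dict[str, ConstitutiveParams] = {
    "ex_vivo_wang": ConstitutiveParams(
        a=0.236, b=10.810, af=20.037, bf=14.154, as_=3.724, bs=5.164,
        afs=0.411, bfs=11.300,
    ),
    "in_vivo_gao": ConstitutiveParams(
        a=0.18, b=2.6, af=3.34, bf=2.73, as_=0.69, bs=1.11, afs=0.31, bfs=2.58,
    ),
}


def reference_vector(label: str) -> ConstitutiveParams:
    try:
        return REFERENCE_VECTORS[label]
    except KeyError:
        raise InvalidParameterError(
            f"unknown reference vector {label!r}; "
            f"choose from {sorted(REFERENCE_VECTORS)}"
        ) from None


def as_theta(theta) -> np.ndarray:
    """Validate a reduced scaling vector theta (4 strictly positive scalars)."""
    t = np.asarray(theta, dtype=float).ravel()
    if t.shape != (4,):
        raise InvalidParameterError(f"theta must have 4 entries, got shape {t.shape}")
    if not np.all(np.isfinite(t)) or np.any(t <= 0.0):
        raise InvalidParameterError(f"theta must be strictly positive, got {t}")
    return t


def descale(theta, ref: ConstitutiveParams | str) -> ConstitutiveParams:
    """Map the reduced scalings theta onto the eight HO parameters.

    t1 scales the matrix pair (a, b), t2 the fibre/sheet stiffnesses
    (af, as), t3 the fibre/sheet exponents (bf, bs) and t4 the shear pair
    (afs, bfs), all relative to the reference vector.
    """
    t = as_theta(theta)
    if isinstance(ref, str):
        ref = reference_vector(ref)
    return ConstitutiveParams(
        a=t[0] * ref.a, b=t[0] * ref.b,
        af=t[1] * ref.af, as_=t[1] * ref.as_,
        bf=t[2] * ref.bf, bs=t[2] * ref.bs,
        afs=t[3] * ref.afs, bfs=t[3] * ref.bfs,
    )


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeformationState:
    """A homogeneous incompressible deformation with material directions.

    ``F`` is the deformation gradient (det F = 1), ``f0`` and ``s0`` the unit
    myocyte and sheet directions in the reference configuration.
    """

    F: np.ndarray
    f0: np.ndarray
    s0: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "F", np.asarray(self.F, dtype=float))
        object.__setattr__(self, "f0", np.asarray(self.f0, dtype=float))
        object.__setattr__(self, "s0", np.asarray(self.s0, dtype=float))
        if self.F.shape != (3, 3):
            raise ValueError("F must be 3x3")
        for name in ("f0", "s0"):
            v = getattr(self, name)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a unit vector")


@dataclass(frozen=True)
class InvariantSet:
    I1: float
    I4f: float
    I4s: float
    I8fs: float


@dataclass(frozen=True)
class StressState:
    """Cauchy stress (kPa, symmetric) and the incompressibility multiplier p."""

    sigma: np.ndarray
    p: float


def invariants(state: DeformationState, det_tol: float = 1e-8) -> InvariantSet:
    """Deformation invariants I1, I4f, I4s, I8fs of C = F^T F."""
    J = np.linalg.det(state.F)
    if abs(J - 1.0) > det_tol:
        raise IncompressibilityError(f"det(F) = {J} departs from 1 beyond {det_tol}")
    C = state.F.T @ state.F
    return InvariantSet(
        I1=float(np.trace(C)),
        I4f=float(state.f0 @ C @ state.f0),
        I4s=float(state.s0 @ C @ state.s0),
        I8fs=float(state.f0 @ C @ state.s0),
    )


# ---------------------------------------------------------------------------
# Energy and stress
# ---------------------------------------------------------------------------

def strain_energy(inv: InvariantSet, params: ConstitutiveParams) -> float:
    """HO strain energy density (kPa); anisotropic terms tension-only."""
    if inv.I4f <= 0.0 or inv.I4s <= 0.0:
        raise ValueError("I4f and I4s must be positive")
    p = params
    e4f = max(inv.I4f - 1.0, 0.0)
    e4s = max(inv.I4s - 1.0, 0.0)
    W = p.a / (2.0 * p.b) * np.exp(p.b * (inv.I1 - 3.0))
    W += p.af / (2.0 * p.bf) * (np.exp(p.bf * e4f**2) - 1.0)
    W += p.as_ / (2.0 * p.bs) * (np.exp(p.bs * e4s**2) - 1.0)
    W += p.afs / (2.0 * p.bfs) * (np.exp(p.bfs * inv.I8fs**2) - 1.0)
    return float(W)


def dW_dI1(I1, params: ConstitutiveParams):
    """psi1 = dW/dI1; array-friendly."""
    return 0.5 * params.a * np.exp(params.b * (np.asarray(I1) - 3.0))


def dW_dI4(I4, a_i: float, b_i: float):
    """psi4 = dW/dI4 for a fibre-family term with the tension-only switch."""
    e = np.maximum(np.asarray(I4) - 1.0, 0.0)
    return a_i * e * np.exp(b_i * e**2)


def dW_dI8(I8, params: ConstitutiveParams):
    """psi8 = dW/dI8fs (active in both shear senses)."""
    I8 = np.asarray(I8)
    return params.afs * I8 * np.exp(params.bfs * I8**2)


def _sigma_active(state: DeformationState, params: ConstitutiveParams) -> np.ndarray:
    """The 'extra' Cauchy stress before the hydrostatic term -p I.

    sigma_hat = 2 psi1 B + 2 psi4f f x f + 2 psi4s s x s + psi8 (f x s + s x f)
    with B = F F^T and the push-forwards f = F f0, s = F s0.
    """
    inv = invariants(state)
    F = state.F
    B = F @ F.T
    f = F @ state.f0
    s = F @ state.s0
    sig = 2.0 * dW_dI1(inv.I1, params) * B
    sig = sig + 2.0 * dW_dI4(inv.I4f, params.af, params.bf) * np.outer(f, f)
    sig = sig + 2.0 * dW_dI4(inv.I4s, params.as_, params.bs) * np.outer(s, s)
    psi8 = dW_dI8(inv.I8fs, params)
    sig = sig + psi8 * (np.outer(f, s) + np.outer(s, f))
    return sig


def cauchy_stress(
    state: DeformationState,
    params: ConstitutiveParams,
    lateral_zero_axes: tuple[int, ...] = (1, 2),
    rtol: float = 1e-6,
) -> StressState:
    """Cauchy stress with the Lagrange multiplier resolved algebraically.

    ``lateral_zero_axes`` lists the coordinate axes whose normal stresses are
    traction-free; p is chosen so those normal stresses vanish.  If the listed
    axes imply mutually inconsistent values of p (beyond ``rtol`` relative to
    the stress scale) the boundary conditions over-determine the homogeneous
    problem and a :class:`ConfigurationError` is raised.
    """
    axes = tuple(lateral_zero_axes)
    if len(axes) == 0:
        raise ConfigurationError("at least one traction-free axis is required")
    if any(ax not in (0, 1, 2) for ax in axes):
        raise ConfigurationError(f"axes must be in (0, 1, 2), got {axes}")
    sig = _sigma_active(state, params)
    candidates = np.array([sig[ax, ax] for ax in axes])
    scale = max(float(np.max(np.abs(sig))), 1.0)
    if np.max(candidates) - np.min(candidates) > rtol * scale:
        raise ConfigurationError(
            "traction-free axes imply inconsistent hydrostatic pressures "
            f"{candidates}; the lateral conditions over-determine p"
        )
    p = float(np.mean(candidates))
    sigma = sig - p * np.eye(3)
    return StressState(sigma=sigma, p=p)


def uniaxial_curve(
    params: ConstitutiveParams,
    direction: str,
    stretch_grid,
) -> np.ndarray:
    """Virtual uniaxial stretch experiment along the myocyte or sheet axis.

    For each stretch lam >= 1 the deformation is the incompressible uniaxial
    state F = diag(lam, lam^-1/2, lam^-1/2) with the probed direction on axis
    1 (myocyte mode: f0 on axis 1, s0 on axis 2; sheet mode: swapped).
    Returns the axial Cauchy stress sigma_11 (kPa) with free lateral faces.
    """
    lam = np.atleast_1d(np.asarray(stretch_grid, dtype=float))
    if np.any(lam < 1.0):
        raise ValueError("stretch grid must satisfy lambda >= 1 (tension only)")
    if direction == "myocyte":
        f0, s0 = np.array([1.0, 0, 0]), np.array([0, 1.0, 0])
    elif direction == "sheet":
        f0, s0 = np.array([0, 1.0, 0]), np.array([1.0, 0, 0])
    else:
        raise ValueError("direction must be 'myocyte' or 'sheet'")
    out = np.empty_like(lam)
    for i, l in enumerate(lam):
        F = np.diag([l, l**-0.5, l**-0.5])
        st = cauchy_stress(DeformationState(F, f0, s0), params, (1, 2))
        out[i] = st.sigma[0, 0]
    return out
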