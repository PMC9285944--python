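"""Idealised left-ventricle passive inflation simulator.

This module is the desk-scale stand-in for a finite-element diastolic filling
solve.  The LV is idealised as a stack of four thick-walled incompressible
cylindrical slices (base to mid-ventricle) with a linearly varying fibre helix
angle across the wall, loaded by a luminal pressure at a fixed axial stretch.
Slice radii taper from base to mid-ventricle, so the slices operate at
different circumferential stretch levels and probe different parts of the
exponentially stiffening stress-stretch response; this is what makes the
reduced material scalings identifiable from a single-pressure observation.

For each slice, incompressibility at fixed axial stretch ``lambda_z`` gives
the through-wall map r(R)^2 = ri^2 + (R^2 - Ri^2)/lambda_z, and radial
equilibrium reduces to a single quadrature for the luminal pressure

    P(ri) = int_{ri}^{ro} (sigma_theta_theta - sigma_rr) / r dr,

in which the incompressibility multiplier cancels.  The inner radius ``ri``
is found by root bracketing so that P(ri) matches the requested pressure.

Crash rule: if the required inner-wall circumferential stretch exceeds the
geometry's ``lambda_max`` (or the root-finder fails), the simulator reports a
crash instead of a result -- mimicking forward-solver failures at parameter
values that violate the model's physiological assumptions.  The crash set is
a deterministic low-stiffness (low theta1) region.

Readouts: cavity volume V (mL) and 24 regional circumferential strains,
six per slice, eps_i = h_i (lambda_theta,mid - 1) where h_i are regional
heterogeneity multipliers near 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml
from scipy.optimize import brentq

from .constitutive import (
    KPA_PER_MMHG,
    ConstitutiveParams,
    descale,
    dW_dI1,
    dW_dI4,
    dW_dI8,
    reference_vector,
)

__all__ = [
    "GeometrySpec",
    "SimulatorResult",
    "CylindricalLVModel",
    "inflate",
    "inflate_params",
    "pv_curve",
    "TOY_GEOMETRIES",
    "toy_geometry",
]

N_REGIONS = 24
N_SLICES = 4
_REGIONS_PER_SLICE = N_REGIONS // N_SLICES


@dataclass(frozen=True)
class GeometrySpec:
    """Idealised LV geometry.

    Lengths in mm, angles in degrees, torsion in rad/mm.  ``taper`` gives the
    per-slice inner-radius multipliers (base to mid-ventricle);
    ``heterogeneity`` the 24 regional strain multipliers h_i; ``lambda_max``
    the inner-wall circumferential stretch beyond which the simulator crashes.
    """

    r_inner: float = 22.0
    #: wall thickness; a scalar, or one value per slice.  Regional thickness
    #: variation makes the slices operate at clearly different wall stretches
    #: under the same pressure, so the observation probes the stiffening
    #: response over a wide strain range (this is what pins the fibre
    #: amplitude and exponent scalings separately).
    wall_thickness: float | tuple[float, ...] = (12.0, 24.0, 18.0, 19.0)
    length: float = 72.0
    #: fibre helix angle at endo/epi wall (linear across the wall); a scalar,
    #: or one value per slice.  The default profile rotates the mean fibre
    #: orientation from circumferential (base) towards longitudinal
    #: (mid-ventricle), emulating base-to-apex fibre architecture variation;
    #: slices whose fibres leave the circumferential direction carry their
    #: hoop load through the isotropic matrix, which is what separates the
    #: matrix scaling from the fibre scalings in the observations.
    helix_endo_deg: float | tuple[float, ...] = (60.0, 60.0, 70.0, 78.0)
    helix_epi_deg: float | tuple[float, ...] = (-60.0, -60.0, -15.0, 15.0)
    torsion_rate: float = 0.0
    sheet_tilt_deg: float = 0.0
    #: fixed axial stretch; a scalar, or one value per slice (a base-to-mid
    #: longitudinal pre-stretch profile, which is also what makes the matrix
    #: and fibre contributions separately identifiable: mid-wall fibres are
    #: nearly circumferential and insensitive to axial stretch, the isotropic
    #: matrix term is not)
    axial_stretch: float | tuple[float, ...] = (1.0, 1.03, 1.09, 1.14)
    #: inner-wall circumferential stretch limit beyond which the forward
    #: solve reports a crash; a scalar, or one value per slice
    lambda_max: float | tuple[float, ...] = (1.63, 1.74, 2.10, 2.60)
    taper: tuple[float, ...] = (1.0, 0.95, 0.85, 0.7)
    #: per-region wall-thickness factors (6 per slice) emulating the regional
    #: thickness variation of a real ventricle (septum thicker than the free
    #: wall); each region then operates at its own wall stretch, so the 24
    #: regional strains probe the stiffening response at 24 strain levels
    region_thickness_factors: tuple[float, ...] = tuple(
        [0.8, 0.9, 1.0, 1.05, 1.15, 1.3] * N_SLICES
    )
    heterogeneity: tuple[float, ...] = tuple([1.0] * N_REGIONS)
    label: str = "default"
    n_quad: int = 32

    def __post_init__(self) -> None:
        if min(self.r_inner, self.length, *self.wall_thicknesses) <= 0:
            raise ValueError("r_inner, wall_thickness and length must be positive")
        if min(self.lambda_maxes) <= 1.0:
            raise ValueError("lambda_max must exceed 1")
        if len(self.taper) != N_SLICES or min(self.taper) <= 0:
            raise ValueError(f"taper needs {N_SLICES} positive multipliers")
        if len(self.heterogeneity) != N_REGIONS or min(self.heterogeneity) <= 0:
            raise ValueError(f"heterogeneity needs {N_REGIONS} positive multipliers")
        if (
            len(self.region_thickness_factors) != N_REGIONS
            or min(self.region_thickness_factors) <= 0
        ):
            raise ValueError(
                f"region_thickness_factors needs {N_REGIONS} positive values"
            )
        lz = self.axial_stretches
        if len(lz) != N_SLICES or min(lz) <= 0:
            raise ValueError(
                f"axial_stretch must be a positive scalar or {N_SLICES} positive values"
            )

    @staticmethod
    def _per_slice(value) -> tuple[float, ...]:
        if np.isscalar(value):
            return (float(value),) * N_SLICES
        out = tuple(float(v) for v in value)
        if len(out) != N_SLICES:
            raise ValueError(f"per-slice fields need {N_SLICES} values")
        return out

    @property
    def axial_stretches(self) -> tuple[float, ...]:
        return self._per_slice(self.axial_stretch)

    @property
    def wall_thicknesses(self) -> tuple[float, ...]:
        return self._per_slice(self.wall_thickness)

    @property
    def lambda_maxes(self) -> tuple[float, ...]:
        return self._per_slice(self.lambda_max)

    @property
    def helix_endo(self) -> tuple[float, ...]:
        return self._per_slice(self.helix_endo_deg)

    @property
    def helix_epi(self) -> tuple[float, ...]:
        return self._per_slice(self.helix_epi_deg)

    # -- serialisation ------------------------------------------------------
    def to_yaml(self, path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in asdict(self).items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @staticmethod
    def from_yaml(path) -> "GeometrySpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d = {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()}
        return GeometrySpec(**d)

    @property
    def reference_volume_ml(self) -> float:
        """Zero-pressure cavity volume (mL)."""
        l_slice = self.length / N_SLICES
        return float(
            np.pi * sum((self.r_inner * t) ** 2 for t in self.taper) * l_slice / 1000.0
        )


@dataclass(frozen=True)
class SimulatorResult:
    """Outcome of one forward solve at a single pressure."""

    status: str                      # "success" | "crash"
    pressure_mmhg: float
    volume_ml: float | None = None
    strains: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.status not in ("success", "crash"):
            raise ValueError("status must be 'success' or 'crash'")
        if self.status == "success":
            if self.volume_ml is None or self.volume_ml <= 0:
                raise ValueError("successful result needs a positive volume")
            s = np.asarray(self.strains, dtype=float)
            if s.shape != (N_REGIONS,):
                raise ValueError(f"successful result needs {N_REGIONS} strains")
            object.__setattr__(self, "strains", s)
        else:
            if self.volume_ml is not None or self.strains is not None:
                raise ValueError("crash results carry no payload")

    @property
    def crashed(self) -> bool:
        return self.status == "crash"


class SimulatorCrash(RuntimeError):
    """Internal signal that a slice solve exceeded the stretch limit."""


class CylindricalLVModel:
    """Passive inflation of the tapered-cylinder LV for one geometry.

    Each of the 24 regions (6 per slice, 4 slices) is a thick-walled sector
    with the slice's inner radius, helix-angle range and axial stretch, but
    its own regional wall thickness; every sector's radial equilibrium is
    solved independently.  `inflate_params` solves all sectors at a given
    pressure for a full HO parameter vector; `inflate` takes reduced
    scalings theta plus a reference vector.
    """

    def __init__(self, geom: GeometrySpec):
        self.geom = geom
        gl_x, gl_w = np.polynomial.legendre.leggauss(geom.n_quad)
        self._sectors = []
        lzs = geom.axial_stretches
        for i in range(N_REGIONS):
            k = i // _REGIONS_PER_SLICE
            Ri = geom.r_inner * geom.taper[k]
            Ro = Ri + geom.wall_thicknesses[k] * geom.region_thickness_factors[i]
            # map Gauss-Legendre nodes from [-1, 1] to [Ri, Ro]
            R = 0.5 * (Ro - Ri) * gl_x + 0.5 * (Ro + Ri)
            w = 0.5 * (Ro - Ri) * gl_w
            frac = (R - Ri) / (Ro - Ri)
            alpha = np.deg2rad(
                geom.helix_endo[k] + frac * (geom.helix_epi[k] - geom.helix_endo[k])
            )
            self._sectors.append(
                {"Ri": Ri, "Ro": Ro, "R": R, "w": w, "alpha": alpha,
                 "lz": lzs[k], "lmax": geom.lambda_maxes[k], "slice": k}
            )
        self._beta = np.deg2rad(geom.sheet_tilt_deg)

    # -- local kinematics, vectorised over wall quadrature nodes ------------
    def _wall_state(self, sl, ri: float):
        """Stretches, shear and fibre geometry across the wall of one sector."""
        lz = sl["lz"]
        R = sl["R"]
        r = np.sqrt(ri**2 + (R**2 - sl["Ri"] ** 2) / lz)
        lam_t = r / R
        lam_r = R / (lz * r)
        gamma = self.geom.torsion_rate * r
        return r, lam_r, lam_t, gamma

    def _pressure_kpa(self, sl, ri: float, params: ConstitutiveParams) -> float:
        """Luminal pressure (kPa) balancing the wall at trial inner radius ri."""
        lz = sl["lz"]
        r, lam_r, lam_t, gamma = self._wall_state(sl, ri)
        alpha = sl["alpha"]
        ca, sa = np.cos(alpha), np.sin(alpha)
        cb, sb = np.cos(self._beta), np.sin(self._beta)

        # deformation gradient per node in the (r, theta, z) orthonormal frame:
        # F = [[lam_r, 0, 0], [0, lam_t, gamma], [0, 0, lz]]
        # material directions: f0 = (0, ca, sa);  s0 = cb e_r + sb (-sa, ca)
        f = np.stack([np.zeros_like(r), lam_t * ca + gamma * sa, lz * sa], axis=-1)
        s = np.stack(
            [cb * lam_r, sb * (-lam_t * sa + gamma * ca), sb * lz * ca], axis=-1
        )

        I1 = lam_r**2 + lam_t**2 + lz**2 + gamma**2
        I4f = np.einsum("ij,ij->i", f, f)
        I4s = np.einsum("ij,ij->i", s, s)
        I8 = np.einsum("ij,ij->i", f, s)

        # extreme trial states may overflow the exponentials; the resulting
        # inf pressure is handled by the bracketing logic
        with np.errstate(over="ignore", invalid="ignore"):
            psi1 = dW_dI1(I1, params)
            psi4f = dW_dI4(I4f, params.af, params.bf)
            psi4s = dW_dI4(I4s, params.as_, params.bs)
            psi8 = dW_dI8(I8, params)

            # sigma_tt - sigma_rr; B_tt = lam_t^2 + gamma^2, B_rr = lam_r^2
            dsig = 2.0 * psi1 * (lam_t**2 + gamma**2 - lam_r**2)
            dsig += 2.0 * psi4f * (f[:, 1] ** 2 - f[:, 0] ** 2)
            dsig += 2.0 * psi4s * (s[:, 1] ** 2 - s[:, 0] ** 2)
            dsig += 2.0 * psi8 * (f[:, 1] * s[:, 1] - f[:, 0] * s[:, 0])

        # int (sigma_tt - sigma_rr)/r dr  with dr = lam_r dR
        return float(np.sum(sl["w"] * dsig / r * lam_r))

    def _solve_sector(self, sl, params: ConstitutiveParams, p_kpa: float) -> float:
        """Inner deformed radius of one sector at pressure p_kpa, or crash."""
        Ri = sl["Ri"]
        lz = sl["lz"]
        if p_kpa == 0.0 and lz == 1.0:
            return Ri
        ri_max = sl["lmax"] * Ri
        g = lambda ri: self._pressure_kpa(sl, ri, params) - p_kpa

        lo = Ri * (1.0 + 1e-12) if lz == 1.0 else Ri * 1e-3
        g_lo, g_hi = g(lo), g(ri_max)
        if g_hi < 0.0:
            raise SimulatorCrash(
                f"stretch limit lambda_max={sl['lmax']} exceeded "
                f"at {p_kpa / KPA_PER_MMHG:.3g} mmHg"
            )
        if g_lo > 0.0:
            if lz == 1.0:
                return Ri  # zero pressure limit
            raise SimulatorCrash("no equilibrium bracket found")
        return brentq(g, lo, ri_max, xtol=1e-10 * Ri, rtol=8.9e-16)

    # -- public API ---------------------------------------------------------
    def inflate_params(
        self, params: ConstitutiveParams, pressure_mmhg: float
    ) -> SimulatorResult:
        if pressure_mmhg < 0:
            raise ValueError("pressure must be non-negative")
        p_kpa = pressure_mmhg * KPA_PER_MMHG
        geom = self.geom
        l_slice = geom.length / N_SLICES
        vol = 0.0
        strains = np.empty(N_REGIONS)
        het = np.asarray(geom.heterogeneity)
        ri2_slice = np.zeros(N_SLICES)
        try:
            for i, sl in enumerate(self._sectors):
                ri = self._solve_sector(sl, params, p_kpa)
                ri2_slice[sl["slice"]] += ri**2 / _REGIONS_PER_SLICE
                R_mid = 0.5 * (sl["Ri"] + sl["Ro"])
                r_mid = np.sqrt(ri**2 + (R_mid**2 - sl["Ri"] ** 2) / sl["lz"])
                strains[i] = het[i] * (r_mid / R_mid - 1.0)
            # cavity volume: per-slice mean squared inner radius of its sectors
            lzs = geom.axial_stretches
            vol = float(np.pi * l_slice * np.sum(ri2_slice * np.asarray(lzs)))
        except SimulatorCrash:
            return SimulatorResult(status="crash", pressure_mmhg=pressure_mmhg)
        return SimulatorResult(
            status="success",
            pressure_mmhg=pressure_mmhg,
            volume_ml=vol / 1000.0,
            strains=strains,
        )

    def inflate(self, theta, ref, pressure_mmhg: float) -> SimulatorResult:
        if isinstance(ref, str):
            ref = reference_vector(ref)
        return self.inflate_params(descale(theta, ref), pressure_mmhg)

    def pv_curve(self, theta, ref, pressure_grid) -> list[SimulatorResult]:
        """One inflate per pressure (ascending); everything after the first
        crash is marked crash without further solves."""
        grid = np.asarray(pressure_grid, dtype=float)
        if np.any(np.diff(grid) < 0):
            raise ValueError("pressure grid must be sorted ascending")
        out: list[SimulatorResult] = []
        crashed = False
        for p in grid:
            if crashed:
                out.append(SimulatorResult(status="crash", pressure_mmhg=float(p)))
                continue
            res = self.inflate(theta, ref, float(p))
            crashed = res.crashed
            out.append(res)
        return out


# module-level functional wrappers -----------------------------------------

def inflate(theta, ref, geom: GeometrySpec, pressure_mmhg: float) -> SimulatorResult:
    return CylindricalLVModel(geom).inflate(theta, ref, pressure_mmhg)


def inflate_params(
    params: ConstitutiveParams, geom: GeometrySpec, pressure_mmhg: float
) -> SimulatorResult:
    return CylindricalLVModel(geom).inflate_params(params, pressure_mmhg)


def pv_curve(theta, ref, geom: GeometrySpec, pressure_grid) -> list[SimulatorResult]:
    return CylindricalLVModel(geom).pv_curve(theta, ref, pressure_grid)


#: Named fixture geometries spanning mild anatomical variability.
TOY_GEOMETRIES: dict[str, GeometrySpec] = {
    "toyA": GeometrySpec(label="toyA"),
    "toyB": GeometrySpec(
        r_inner=20.5, wall_thickness=(11.0, 22.0, 17.0, 18.0), length=68.0,
        helix_endo_deg=(56.0, 58.0, 68.0, 77.0),
        helix_epi_deg=(-56.0, -58.0, -18.0, 12.0), label="toyB",
    ),
    "toyC": GeometrySpec(
        r_inner=23.5, wall_thickness=(13.0, 26.0, 19.0, 20.0), length=78.0,
        torsion_rate=0.004, sheet_tilt_deg=10.0, label="toyC",
    ),
    "toyD": GeometrySpec(
        r_inner=21.5, wall_thickness=(12.5, 25.0, 18.5, 19.5), length=70.0,
        helix_endo_deg=(62.0, 62.0, 72.0, 80.0),
        helix_epi_deg=(-62.0, -58.0, -12.0, 18.0),
        torsion_rate=0.003, sheet_tilt_deg=8.0,
        taper=(1.0, 0.94, 0.86, 0.72), label="toyD",
    ),
}


def toy_geometry(label: str) -> GeometrySpec:
    try:
        return TOY_GEOMETRIES[label]
    except KeyError:
        raise KeyError(
            f"unknown toy geometry {label!r}; choose from {sorted(TOY_GEOMETRIES)}"
        ) from None
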