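"""Holzapfel-Ogden law: reference vectors, invariants, energy and stress."""

import numpy as np
import pytest

from cardiobo.constitutive import (
    ConstitutiveParams,
    DeformationState,
    InvariantSet,
    ConfigurationError,
    IncompressibilityError,
    InvalidParameterError,
    REFERENCE_VECTORS,
    cauchy_stress,
    descale,
    invariants,
    reference_vector,
    strain_energy,
    uniaxial_curve,
)
from conftest import random_unimodular

E1, E2 = np.array([1.0, 0, 0]), np.array([0, 1.0, 0])


class TestDescale:
    def test_unit_scalings_reproduce_reference_exactly(self):
        for label, ref in REFERENCE_VECTORS.items():
            assert descale((1, 1, 1, 1), label) == ref

    def test_table_values(self):
        wang = descale((1, 1, 1, 1), "ex_vivo_wang")
        assert wang.af == pytest.approx(20.037, abs=0)
        gao = descale((1, 1, 1, 1), "in_vivo_gao")
        assert gao.b == pytest.approx(2.6, abs=0)

    def test_group_scaling(self):
        p = descale((2, 1, 1, 1), "ex_vivo_wang")
        assert p.a == pytest.approx(0.472)
        assert p.b == pytest.approx(21.620)
        # other groups untouched
        assert p.af == pytest.approx(20.037)
        assert p.bfs == pytest.approx(11.300)

    @pytest.mark.parametrize("theta", [(0, 1, 1, 1), (1, -2, 1, 1), (1, 1, 1)])
    def test_invalid_theta_rejected(self, theta):
        with pytest.raises(InvalidParameterError):
            descale(theta, "in_vivo_gao")

    def test_unknown_preset_rejected(self):
        with pytest.raises(InvalidParameterError):
            reference_vector("nope")


class TestInvariants:
    def test_identity(self):
        inv = invariants(DeformationState(np.eye(3), E1, E2))
        assert (inv.I1, inv.I4f, inv.I4s, inv.I8fs) == (3.0, 1.0, 1.0, 0.0)

    def test_uniaxial(self):
        F = np.diag([1.2, 1.2**-0.5, 1.2**-0.5])
        inv = invariants(DeformationState(F, E1, E2))
        assert inv.I4f == pytest.approx(1.44)
        assert inv.I1 == pytest.approx(1.44 + 2.0 / 1.2)

    def test_simple_shear(self):
        F = np.eye(3) + 0.1 * np.outer(E1, E2)
        inv = invariants(DeformationState(F, E1, E2))
        assert inv.I8fs == pytest.approx(0.1)

    def test_non_unimodular_rejected(self):
        with pytest.raises(IncompressibilityError):
            invariants(DeformationState(2.0 * np.eye(3), E1, E2))

    def test_i1_at_least_3_for_unimodular(self, rng):
        # AM-GM on the singular values: tr(C) >= 3 det(F)^(2/3)
        for _ in range(50):
            F = random_unimodular(rng)
            inv = invariants(DeformationState(F, E1, E2))
            assert inv.I1 >= 3.0 - 1e-9


class TestStrainEnergy:
    def test_reference_state_value(self):
        inv = InvariantSet(I1=3.0, I4f=1.0, I4s=1.0, I8fs=0.0)
        gao = reference_vector("in_vivo_gao")
        assert strain_energy(inv, gao) == pytest.approx(0.18 / 5.2)

    def test_fibre_compression_inactive(self):
        gao = reference_vector("in_vivo_gao")
        w_ref = strain_energy(InvariantSet(3.0, 1.0, 1.0, 0.0), gao)
        w_cmp = strain_energy(InvariantSet(3.0, 0.9, 1.0, 0.0), gao)
        assert w_cmp == w_ref

    def test_shear_term_vanishes_with_afs(self):
        inv = InvariantSet(3.0, 1.0, 1.0, 0.3)
        p_small = ConstitutiveParams(0.2, 2.0, 3.0, 2.0, 0.7, 1.0, 1e-12, 2.0)
        p_ref = ConstitutiveParams(0.2, 2.0, 3.0, 2.0, 0.7, 1.0, 1e-12, 2.0)
        w = strain_energy(inv, p_small)
        w_noshear = strain_energy(InvariantSet(3.0, 1.0, 1.0, 0.0), p_ref)
        assert w == pytest.approx(w_noshear, abs=1e-10)

    def test_nonnegative_on_random_states(self, rng):
        gao = reference_vector("in_vivo_gao")
        for _ in range(50):
            F = random_unimodular(rng)
            inv = invariants(DeformationState(F, E1, E2))
            assert strain_energy(inv, gao) >= 0.0


def _fd_stress(F, f0, s0, params, h=1e-6):
    """Finite-difference (dW/dF) F^T for the energy-consistency oracle."""
    from cardiobo.constitutive import strain_energy as W

    def energy(Fm):
        C = Fm.T @ Fm
        inv = InvariantSet(
            float(np.trace(C)), float(f0 @ C @ f0), float(s0 @ C @ s0),
            float(f0 @ C @ s0),
        )
        return W(inv, params)

    dWdF = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Fp, Fm_ = F.copy(), F.copy()
            Fp[i, j] += h
            Fm_[i, j] -= h
            dWdF[i, j] = (energy(Fp) - energy(Fm_)) / (2 * h)
    return dWdF @ F.T


class TestCauchyStress:
    def test_stress_free_reference(self):
        st = cauchy_stress(
            DeformationState(np.eye(3), E1, E2), reference_vector("in_vivo_gao")
        )
        assert np.allclose(st.sigma, 0.0, atol=1e-12)

    def test_uniaxial_signs(self):
        gao = reference_vector("in_vivo_gao")
        lam = 1.1
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        st = cauchy_stress(DeformationState(F, E1, E2), gao, (1, 2))
        assert st.sigma[0, 0] > 0
        assert st.sigma[1, 1] == pytest.approx(0.0, abs=1e-12)
        assert st.sigma[2, 2] == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_on_random_deformations(self, rng):
        gao = reference_vector("in_vivo_gao")
        for _ in range(20):
            F = random_unimodular(rng)
            st = cauchy_stress(DeformationState(F, E1, E2), gao, (2,))
            assert np.allclose(st.sigma, st.sigma.T, atol=1e-9)

    def test_energy_consistency_finite_difference(self, rng):
        """sigma + p I must equal (dW/dF) F^T on random unimodular states."""
        gao = reference_vector("in_vivo_gao")
        n_checked = 0
        for _ in range(100):
            F = random_unimodular(rng, scale=0.15)
            state = DeformationState(F, E1, E2)
            inv = invariants(state)
            # skip states close to a tension-only kink where FD is one-sided
            if abs(inv.I4f - 1) < 5e-3 or abs(inv.I4s - 1) < 5e-3:
                continue
            st = cauchy_stress(state, gao, (2,))
            sig_active = st.sigma + st.p * np.eye(3)
            oracle = _fd_stress(F, E1, E2, gao)
            scale = max(np.max(np.abs(oracle)), 1e-3)
            assert np.max(np.abs(sig_active - oracle)) / scale < 1e-5
            n_checked += 1
        assert n_checked >= 80

    def test_overdetermined_lateral_conditions_rejected(self):
        wang = reference_vector("ex_vivo_wang")
        lam = 1.2
        # stretching along the fibre: axis 0 stress cannot also vanish
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        with pytest.raises(ConfigurationError):
            cauchy_stress(DeformationState(F, E1, E2), wang, (0, 1, 2))


class TestUniaxialCurve:
    def test_zero_stress_at_unit_stretch(self):
        gao = reference_vector("in_vivo_gao")
        assert uniaxial_curve(gao, "myocyte", [1.0])[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("label", ["ex_vivo_wang", "in_vivo_gao"])
    @pytest.mark.parametrize("direction", ["myocyte", "sheet"])
    def test_strictly_increasing(self, label, direction):
        lam = np.linspace(1.0, 1.3, 61)
        s = uniaxial_curve(reference_vector(label), direction, lam)
        assert np.all(np.diff(s) > 0)
        assert np.all(s >= 0)

    def test_myocyte_stiffer_than_sheet_for_wang(self):
        wang = reference_vector("ex_vivo_wang")
        m = uniaxial_curve(wang, "myocyte", [1.15])[0]
        s = uniaxial_curve(wang, "sheet", [1.15])[0]
        assert m > s

    def test_compressive_grid_rejected(self):
        with pytest.raises(ValueError):
            uniaxial_curve(reference_vector("in_vivo_gao"), "myocyte", [0.9, 1.0])
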