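"""Constitutive laws: Yeoh specialisations against finite-difference oracles,
and the flag-shaped superelastic Nitinol state machine."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tevarsim as tv
from tevarsim.materials import Branch, DomainError, InvalidStateError


# ---------------------------------------------------------------------------
# Yeoh energy and stress specialisations
# ---------------------------------------------------------------------------


def uniaxial_energy(lam, params):
    return tv.yeoh_energy(lam**2 + 2.0 / lam, params)


def ring_energy(lam, params):
    return tv.yeoh_energy(lam**2 + 1.0 + lam**-2, params)


class TestYeohEnergy:
    def test_zero_at_reference(self, wall):
        assert tv.yeoh_energy(3.0, wall) == 0.0

    def test_cubic_polynomial_hand_value(self, wall):
        x = 0.106667
        expected = 17.5 * x + 58.9 * x**2 + 116.1 * x**3
        assert tv.yeoh_energy(3.0 + x, wall) == pytest.approx(expected, rel=1e-12)

    def test_neo_hookean_reduction(self):
        assert tv.yeoh_energy(4.0, tv.YeohParams(1.0, 0.0, 0.0)) == pytest.approx(1.0)

    def test_domain_error_below_3(self, wall):
        with pytest.raises(DomainError):
            tv.yeoh_energy(2.9, wall)

    def test_c10_must_be_positive(self):
        with pytest.raises(ValueError):
            tv.YeohParams(-1.0, 0.0, 0.0)


class TestYeohStress:
    def test_stress_free_reference(self, wall):
        assert tv.yeoh_uniaxial_cauchy(1.0, wall) == pytest.approx(0.0, abs=1e-12)
        assert tv.yeoh_ring_hoop_cauchy(1.0, wall) == pytest.approx(0.0, abs=1e-12)

    def test_neo_hookean_hand_value(self):
        nh = tv.YeohParams(1.0, 0.0, 0.0)
        lam = 1.05
        assert tv.yeoh_uniaxial_cauchy(lam, nh) == pytest.approx(
            2.0 * (lam**2 - 1.0 / lam), rel=1e-12
        )

    def test_positive_stretch_required(self, wall):
        with pytest.raises(DomainError):
            tv.yeoh_uniaxial_cauchy(-0.5, wall)
        with pytest.raises(DomainError):
            tv.yeoh_ring_hoop_cauchy(0.0, wall)

    def test_monotone_increasing_in_tension(self, wall):
        lam = np.linspace(1.0, 1.6, 200)
        assert np.all(np.diff(tv.yeoh_uniaxial_cauchy(lam, wall)) > 0)

    def test_ring_small_strain_slope_is_8c10(self, wall):
        h = 1e-7
        slope = tv.yeoh_ring_hoop_cauchy(1.0 + h, wall) / h
        assert slope == pytest.approx(8.0 * wall.c10, rel=1e-5)

    @pytest.mark.parametrize("lam", [1.01, 1.05, 1.1, 1.2, 1.3, 1.45])
    def test_uniaxial_matches_energy_derivative(self, wall, lam):
        # sigma = lam * dW/dlam along the incompressible uniaxial path
        h = 1e-6
        fd = lam * (uniaxial_energy(lam + h, wall) - uniaxial_energy(lam - h, wall)) / (2 * h)
        assert tv.yeoh_uniaxial_cauchy(lam, wall) == pytest.approx(fd, rel=1e-6)

    @pytest.mark.parametrize("lam", [1.01, 1.05, 1.1, 1.2, 1.3, 1.45])
    def test_ring_matches_energy_derivative(self, wall, lam):
        h = 1e-6
        fd = lam * (ring_energy(lam + h, wall) - ring_energy(lam - h, wall)) / (2 * h)
        assert tv.yeoh_ring_hoop_cauchy(lam, wall) == pytest.approx(fd, rel=1e-6)

    @given(
        c10=st.floats(1.0, 200.0),
        c20=st.floats(0.0, 500.0),
        c30=st.floats(0.0, 1000.0),
        lam=st.floats(1.02, 1.5),
    )
    def test_energy_consistency_any_parameters(self, c10, c20, c30, lam):
        p = tv.YeohParams(c10, c20, c30)
        h = 1e-6
        fd = lam * (uniaxial_energy(lam + h, p) - uniaxial_energy(lam - h, p)) / (2 * h)
        assert tv.yeoh_uniaxial_cauchy(lam, p) == pytest.approx(fd, rel=1e-5)


class TestLinearElastic:
    def test_linearity(self):
        flap = tv.FLAP_LINEAR
        assert tv.linear_stress(0.0, flap) == 0.0
        assert tv.linear_stress(0.1, flap) == pytest.approx(27.7)
        assert tv.linear_stress(-0.1, flap) == pytest.approx(-27.7)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            tv.LinearElasticParams(E=-1.0)
        with pytest.raises(ValueError):
            tv.LinearElasticParams(E=100.0, nu=0.6)


# ---------------------------------------------------------------------------
# Superelastic Nitinol
# ---------------------------------------------------------------------------


def drive(strains, params, state=None):
    return tv.nitinol_strain_path(strains, params, state)


def load_to_full_martensite(params, eps=0.085):
    _, _, st = drive(np.linspace(0.0, eps, 500), params)
    assert st.xi == 1.0
    return st


class TestNitinol:
    def test_parameter_invariants_enforced(self):
        with pytest.raises(ValueError):
            tv.NitinolParams(sigma_Ls=700.0, sigma_LE=670.0)
        with pytest.raises(ValueError):
            tv.NitinolParams(eps_L=1.5)

    def test_invalid_state_rejected(self, nitinol):
        with pytest.raises(InvalidStateError):
            tv.nitinol_step(tv.NitinolState(xi=1.5), 1e-4, nitinol)

    def test_pure_austenite_elasticity(self, nitinol):
        st = tv.nitinol_step(tv.NitinolState(), 0.005, nitinol)
        assert st.stress == pytest.approx(0.005 * 51700.0)
        assert st.xi == 0.0
        assert st.branch == Branch.AUSTENITE

    def test_forward_transformation_onset_stress(self, nitinol):
        st = tv.NitinolState()
        e = 0.0
        while st.xi == 0.0:
            e += 1e-5
            st = tv.nitinol_step(st, e - st.strain, nitinol)
        assert nitinol.sigma_Ls <= st.stress <= nitinol.sigma_Ls + 0.05

    def test_forward_plateau_stress_bounds(self, nitinol):
        stresses, xis, _ = drive(np.linspace(0.0, 0.085, 2000), nitinol)
        on_plateau = (xis > 0) & (xis < 1)
        assert on_plateau.any()
        assert np.all(stresses[on_plateau] >= nitinol.sigma_Ls - 1e-9)
        assert np.all(stresses[on_plateau] <= nitinol.sigma_LE + 1e-9)

    def test_reverse_plateau_stress_bounds(self, nitinol):
        st = load_to_full_martensite(nitinol)
        stresses, xis, _ = drive(np.linspace(st.strain, 0.0, 2000), nitinol, st)
        on_plateau = (xis > 0) & (xis < 1)
        assert on_plateau.any()
        assert np.all(stresses[on_plateau] >= nitinol.sigma_UE - 1e-9)
        assert np.all(stresses[on_plateau] <= nitinol.sigma_Us + 1e-9)

    def test_superelastic_recovery_closes_exactly(self, nitinol):
        st = load_to_full_martensite(nitinol)
        _, _, back = drive(np.linspace(st.strain, 0.0, 800), nitinol, st)
        assert back.strain == 0.0
        assert back.stress == pytest.approx(0.0, abs=1e-9)
        assert back.xi == 0.0

    def test_transformation_strain_at_completion(self, nitinol):
        st = load_to_full_martensite(nitinol)
        assert st.strain - st.stress / nitinol.E_M == pytest.approx(nitinol.eps_L, abs=1e-12)

    def test_elastic_substepping_is_exact(self, nitinol):
        one = tv.nitinol_step(tv.NitinolState(), 0.004, nitinol)
        st = tv.NitinolState()
        for _ in range(10):
            st = tv.nitinol_step(st, 0.0004, nitinol)
        assert abs(st.stress - one.stress) < 1e-9
        assert abs(st.strain - one.strain) < 1e-15

    def test_monotone_substepping_is_exact_across_plateau(self, nitinol):
        one = tv.nitinol_step(tv.NitinolState(), 0.05, nitinol)
        _, _, many = drive(np.linspace(0.0, 0.05, 1000), nitinol)
        assert abs(many.stress - one.stress) < 1e-8
        assert abs(many.xi - one.xi) < 1e-10

    def test_hysteresis_loop_dissipation_matches_analytic_path(self, nitinol):
        """Loop area from the state machine equals the area computed from the
        closed-form piecewise loading/unloading paths, within 1%."""
        p = nitinol
        eps_max = 0.085

        def path_area(strain_of_xi, sigma_of_xi, eps_elastic_end, slope_end):
            # piecewise parametric path 0 -> eps_max, integrated by fine sampling
            xi = np.linspace(0.0, 1.0, 20000)
            e_plateau = sigma_of_xi(xi) / (p.E_A + xi * (p.E_M - p.E_A)) + xi * p.eps_L
            s_plateau = sigma_of_xi(xi)
            e0 = np.linspace(0.0, e_plateau[0], 2000)
            s0 = slope_end[0] * e0
            e1 = np.linspace(e_plateau[-1], eps_max, 2000)
            s1 = p.E_M * (e1 - p.eps_L)
            e = np.concatenate([e0, e_plateau, e1])
            s = np.concatenate([s0, s_plateau, s1])
            return np.trapezoid(s, e)

        a_load = path_area(None, lambda x: p.sigma_Ls + x * (p.sigma_LE - p.sigma_Ls), None, (p.E_A,))
        a_unload = path_area(None, lambda x: p.sigma_UE + x * (p.sigma_Us - p.sigma_UE), None, (p.E_A,))
        analytic = a_load - a_unload
        assert analytic > 0

        up = np.linspace(0.0, eps_max, 6000)
        s_up, _, st = drive(up, nitinol)
        s_dn, _, _ = drive(up[::-1], nitinol, st)
        numeric = np.trapezoid(s_up, up) - np.trapezoid(s_dn[::-1], up)
        assert numeric == pytest.approx(analytic, rel=0.01)

    def test_stress_controlled_query(self, nitinol):
        st = tv.materials.nitinol_drive_to_stress(tv.NitinolState(), 300.0, nitinol, direction=1)
        assert st.stress == pytest.approx(300.0, abs=1e-6)
        assert st.strain == pytest.approx(300.0 / nitinol.E_A, rel=1e-9)
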