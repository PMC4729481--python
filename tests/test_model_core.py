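"""Unit tests for the force/flux/balance equations and their invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import odeint

import cationflux as cf
from cationflux.model_core import (
    ATPParams,
    CoefficientMatrix,
    ConcentrationError,
    ConfigurationError,
    DynamicCoefficient,
    Geometry,
    IONS,
    Model,
    SystemState,
    buffering_factor,
    live_matrix,
)

R = 8.31446261815324
F = 96485.0


@pytest.fixture()
def geom() -> Geometry:
    return Geometry(surf=2.29e-5, v_in=1.8e-11, v_out=2.85e-6, temperature=296.0)


# ---------------------------------------------------------------------------
# electrochemical force
# ---------------------------------------------------------------------------

class TestElectrochemicalForce:
    def test_zero_at_equal_concentrations_and_zero_potential(self, geom):
        ion = IONS[1]  # K+
        assert cf.electrochemical_force(ion, 0.1, 0.1, 0.0, geom) == 0.0

    def test_nernst_equilibrium_by_construction(self, geom):
        # a 100-fold gradient is exactly balanced by the Nernst potential
        dphi = -(R * geom.temperature / F) * math.log(100.0)
        ion = IONS[1]
        force = cf.electrochemical_force(ion, 100.0, 1.0, dphi, geom)
        assert force == pytest.approx(0.0, abs=1e-12)

    def test_pure_electrical_term(self, geom):
        # equal concentrations, dphi = -0.168 V: force is F*dphi/T alone
        expected = 96485.0 * (-0.168) / 296.0  # independent arithmetic
        ion = IONS[0]
        force = cf.electrochemical_force(ion, 5.0, 5.0, -0.168, geom)
        assert force == pytest.approx(expected, rel=1e-12)

    def test_anion_charge_flips_electrical_term(self, geom):
        cl = IONS[3]
        k = IONS[1]
        fk = cf.electrochemical_force(k, 1.0, 1.0, -0.1, geom)
        fcl = cf.electrochemical_force(cl, 1.0, 1.0, -0.1, geom)
        assert fcl == pytest.approx(-fk)

    def test_nonpositive_concentration_names_ion(self, geom):
        with pytest.raises(ConcentrationError, match="Na"):
            cf.electrochemical_force(IONS[2], -1.0, 0.1, 0.0, geom)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        c_in=st.floats(1e-6, 1e3),
        c_out=st.floats(1e-6, 1e3),
        dphi=st.floats(-0.3, 0.3),
    )
    def test_antisymmetric_in_compartment_swap_at_zero_potential(self, c_in, c_out, dphi):
        geom = Geometry(surf=2.29e-5, v_in=1.8e-11, v_out=2.85e-6)
        ion = IONS[1]
        f1 = cf.electrochemical_force(ion, c_in, c_out, 0.0, geom)
        f2 = cf.electrochemical_force(ion, c_out, c_in, 0.0, geom)
        assert f1 == pytest.approx(-f2, abs=1e-9)


# ---------------------------------------------------------------------------
# ATP affinity and balance
# ---------------------------------------------------------------------------

class TestATP:
    def test_affinity_zero_at_equilibrium(self, geom):
        atp = ATPParams(c_atp_eq=0.316, k_eq=1e-6, atp_stimulus=2.5, k_atp_incr=10.0)
        assert cf.atp_affinity(atp, 0.316, geom) == 0.0

    def test_affinity_reduces_without_equilibrium_constant(self, geom):
        atp = ATPParams(c_atp_eq=0.5, k_eq=0.0, atp_stimulus=2.5, k_atp_incr=1.0)
        c = 1.7
        expected = R * geom.temperature * (c - 0.5) / 0.5
        assert cf.atp_affinity(atp, c, geom) == pytest.approx(expected, rel=1e-12)

    def test_affinity_p2a_value(self, geom):
        # direct arithmetic oracle with the P2a table values
        atp = ATPParams(c_atp_eq=0.316, k_eq=1e-6, atp_stimulus=2.5, k_atp_incr=10.0)
        expected = (8.31446261815324 * 296.0 / 0.316) * (2.477 - 0.316) * (1.0 + 1e-6)
        assert cf.atp_affinity(atp, 2.477, geom) == pytest.approx(expected, rel=1e-12)

    def test_affinity_requires_positive_equilibrium_concentration(self):
        with pytest.raises(ConfigurationError):
            ATPParams(c_atp_eq=0.0, k_eq=0.0, atp_stimulus=2.5, k_atp_incr=1.0)

    def test_derivative_fixed_point_at_stimulus_level(self):
        atp = ATPParams(c_atp_eq=0.316, k_eq=1e-6, atp_stimulus=2.5, k_atp_incr=10.0)
        assert cf.atp_derivative(atp, 2.5) == pytest.approx(0.0, abs=1e-14)

    def test_derivative_zero_before_glucose(self):
        atp = ATPParams(c_atp_eq=0.316, k_eq=1e-6, atp_stimulus=2.5, k_atp_incr=10.0)
        assert cf.atp_derivative(atp, 1.234, glucose_active=False) == 0.0

    def test_derivative_at_zero_concentration_is_production_rate(self):
        atp = ATPParams(c_atp_eq=0.316, k_eq=1e-6, atp_stimulus=2.5, k_atp_incr=10.0)
        assert cf.atp_derivative(atp, 0.0) == pytest.approx(10.0)


# ---------------------------------------------------------------------------
# fluxes
# ---------------------------------------------------------------------------

def _state_for(matrix: CoefficientMatrix, values: dict, geom: Geometry) -> SystemState:
    from cationflux.model_core import StateLayout

    layout = StateLayout(tuple(k for k, _ in matrix.dynamic_items))
    y = np.empty(layout.size)
    for ion in ("H", "K", "Na", "Cl"):
        y[layout.c_out(ion)] = values[f"{ion}_out"]
        y[layout.c_in(ion)] = values[f"{ion}_in"]
    y[layout.I_DPHI] = values["dphi"]
    y[layout.I_ATP] = values["ATP"]
    for k, (_, coef) in enumerate(matrix.dynamic_items):
        y[layout.N_FIXED + k] = coef.init_value
    return SystemState(layout, y)


class TestIonFluxes:
    def test_all_zero_forces_give_zero_fluxes(self, geom):
        matrix = CoefficientMatrix({("H", "H"): 1e-7, ("K", "K"): 1e-8, ("H", "Cl"): 3e-8})
        atp = ATPParams(c_atp_eq=0.3, k_eq=0.0, atp_stimulus=2.5, k_atp_incr=0.0)
        model = Model(geom, matrix, atp, bf=100.0)
        vals = dict(H_out=1.0, H_in=1.0, K_out=2.0, K_in=2.0, Na_out=3.0, Na_in=3.0,
                    Cl_out=4.0, Cl_in=4.0, dphi=0.0, ATP=0.3)
        state = _state_for(matrix, vals, geom)
        J = cf.ion_fluxes(state, matrix, model)
        assert np.allclose(J, 0.0)

    def test_single_channel_case(self, geom):
        matrix = CoefficientMatrix({("K", "K"): 2e-8})
        atp = ATPParams(c_atp_eq=0.3, k_eq=0.0, atp_stimulus=2.5, k_atp_incr=0.0)
        model = Model(geom, matrix, atp, bf=100.0)
        vals = dict(H_out=1.0, H_in=1.0, K_out=0.1, K_in=100.0, Na_out=3.0, Na_in=3.0,
                    Cl_out=4.0, Cl_in=4.0, dphi=0.0, ATP=0.3)
        state = _state_for(matrix, vals, geom)
        J = cf.ion_fluxes(state, matrix, model)
        x_k = R * math.log(100.0 / 0.1)
        assert J[1] == pytest.approx(2e-8 * x_k, rel=1e-12)
        assert np.allclose(np.delete(J, 1), 0.0)

    def test_against_dense_matvec_oracle(self, p2a):
        # brute-force 5x5 product, independently of the flux implementation
        rng = np.random.default_rng(42)
        matrix = p2a.matrix
        vals = dict(
            H_out=3.162e-3 * rng.uniform(0.5, 2), H_in=3.06e-3 * rng.uniform(0.5, 2),
            K_out=0.1 * rng.uniform(0.5, 2), K_in=75.54 * rng.uniform(0.5, 2),
            Na_out=0.01, Na_in=29.98, Cl_out=0.1, Cl_in=0.545,
            dphi=-0.168, ATP=2.477,
        )
        geom = p2a.geometry
        model = p2a.model()
        state = _state_for(matrix, vals, geom)

        # oracle: recompute forces and L explicitly, loop over entries
        z = {"H": 1, "K": 1, "Na": 1, "Cl": -1}
        X = []
        for ion in ("H", "K", "Na", "Cl"):
            X.append(R * math.log(vals[f"{ion}_in"] / vals[f"{ion}_out"])
                     + z[ion] * F * vals["dphi"] / 296.0)
        X.append((R / 0.316) * (vals["ATP"] - 0.316) * (1 + 1e-6))
        names = ("H", "K", "Na", "Cl", "Ar")
        expected = np.zeros(5)
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                entry = matrix.get(a, b)
                value = entry.init_value if isinstance(entry, DynamicCoefficient) else entry
                expected[i] += value * X[j]

        J = cf.ion_fluxes(state, matrix, model)
        assert np.allclose(J, expected, rtol=1e-10)

    def test_asymmetric_matrix_impossible_by_construction(self):
        # both orders address the same stored entry
        m = CoefficientMatrix({("K", "H"): 3e-9})
        assert m.get("H", "K") == m.get("K", "H") == 3e-9

    def test_negative_straight_coefficient_rejected(self):
        with pytest.raises(ConfigurationError):
            CoefficientMatrix({("K", "K"): -1e-9})


class TestConcentrationDerivatives:
    def test_mass_conservation_by_construction(self, geom):
        fluxes = np.array([1e-7, -2e-7, 3e-8, -4e-8, 0.0])
        d = cf.concentration_derivatives(fluxes, geom, bf=50.0)
        for i in (1, 2, 3):  # K, Na, Cl (H is buffered)
            total = geom.v_out * d[2 * i] + geom.v_in * d[2 * i + 1]
            assert total == pytest.approx(0.0, abs=1e-25)

    def test_zero_flux_zero_derivatives(self, geom):
        d = cf.concentration_derivatives(np.zeros(5), geom, bf=10.0)
        assert np.allclose(d, 0.0)

    def test_unit_buffering_reduces_to_unbuffered_form(self, geom):
        fluxes = np.array([5e-8, 0, 0, 0, 0])
        d = cf.concentration_derivatives(fluxes, geom, bf=1.0)
        assert d[1] == pytest.approx(-5e-8 * geom.surf / geom.v_in, rel=1e-12)


class TestDynamicCoefficient:
    def test_fixed_point(self):
        c = DynamicCoefficient(init_value=1e-7, target_aG=5e-1, k_incr=1e-6)
        assert cf.coefficient_derivative(c, 5e-1) == pytest.approx(0.0, abs=1e-20)

    def test_inactive_is_frozen(self):
        c = DynamicCoefficient(init_value=1e-7, target_aG=5e-1, k_incr=1e-6)
        assert cf.coefficient_derivative(c, 1e-7, active=False) == 0.0

    def test_decr_rate_identity(self):
        c = DynamicCoefficient(init_value=0.0, target_aG=0.579, k_incr=1.08e-6)
        assert c.k_decr * c.target_aG == pytest.approx(c.k_incr, rel=1e-15)

    def test_closed_form_relaxation_matches_numerical_integration(self):
        c = DynamicCoefficient(init_value=1e-7, target_aG=2e-4, k_incr=1e-5)
        t = np.linspace(0.0, 100.0, 21)
        numeric = odeint(
            lambda L, _t: cf.coefficient_derivative(c, float(L[0])), c.init_value, t,
            rtol=1e-10, atol=1e-14,
        ).ravel()
        closed = c.target_aG + (c.init_value - c.target_aG) * np.exp(-c.k_decr * t)
        assert np.allclose(numeric, closed, rtol=1e-7)

    def test_zero_target_with_nonzero_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            DynamicCoefficient(init_value=0.0, target_aG=0.0, k_incr=1.0)


class TestMembranePotential:
    def test_electroneutral_fluxes_give_zero(self, geom):
        fluxes = np.array([1e-8, 2e-8, 3e-8, 6e-8, 0.0])  # cations sum equals anion
        assert cf.membrane_potential_derivative(fluxes, geom) == pytest.approx(0.0, abs=1e-12)

    def test_outward_cation_flux_hyperpolarizes(self, geom):
        fluxes = np.array([1e-8, 0, 0, 0, 0.0])
        assert cf.membrane_potential_derivative(fluxes, geom) < 0

    def test_arithmetic_value(self, geom):
        fluxes = np.array([1e-9, 1e-9, 0.0, 0.0, 0.0])
        expected = -2.0 * 96485.0 * 2e-9 / 0.01  # independent arithmetic
        assert cf.membrane_potential_derivative(fluxes, geom) == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# assembled right-hand side
# ---------------------------------------------------------------------------

class TestRHS:
    def test_zero_force_equilibrium_is_fixed_point(self, geom):
        matrix = CoefficientMatrix({("H", "H"): 1e-7, ("K", "K"): 1e-8})
        atp = ATPParams(c_atp_eq=0.3, k_eq=0.0, atp_stimulus=2.5, k_atp_incr=5.0)
        model = Model(geom, matrix, atp, bf=100.0, glucose_active=False)
        vals = dict(H_out=1.0, H_in=1.0, K_out=2.0, K_in=2.0, Na_out=3.0, Na_in=3.0,
                    Cl_out=4.0, Cl_in=4.0, dphi=0.0, ATP=0.3)
        y = _state_for(matrix, vals, geom).vector
        assert np.allclose(cf.rhs(0.0, y, model), 0.0)

    def test_pure_function_of_state(self, p2a):
        model = p2a.model(glucose_active=True)
        y = p2a.initial_state().vector
        d1 = cf.rhs(10.0, y, model)
        d2 = cf.rhs(10.0, y, model)
        assert np.array_equal(d1, d2)

    def test_matches_independent_monolithic_implementation(self, p2a):
        """Duplicate-implementation oracle: the whole P2a right-hand side coded
        flat from the printed table values, without any package machinery."""
        rng = np.random.default_rng(3)
        y = p2a.initial_state().vector.copy()
        y[:8] *= rng.uniform(0.8, 1.2, size=8)
        y[9] = 1.9
        y[10] = 5e-7  # live L_HH
        y[11] = 1e-5  # live L_HAr

        def oracle(y):
            Ho, Hi, Ko, Ki, Nao, Nai, Clo, Cli, dphi, atp, LHH, LHAr = y
            T, Surf, Vin, Vout, pbc, Cm = 296.0, 2.29e-5, 1.8e-11, 2.85e-6, 200.0, 0.01
            XH = R * math.log(Hi / Ho) + F * dphi / T
            XK = R * math.log(Ki / Ko) + F * dphi / T
            XNa = R * math.log(Nai / Nao) + F * dphi / T
            XCl = R * math.log(Cli / Clo) - F * dphi / T
            XAr = (R / 0.316) * (atp - 0.316) * (1 + 1e-6)
            JH = LHH * XH - 1.9e-12 * XNa + 3.84e-7 * XCl + LHAr * XAr
            JK = 1.88e-8 * XK
            JNa = -1.9e-12 * XH + 8.98e-13 * XNa
            JCl = 3.84e-7 * XH + 3.08e-7 * XCl
            Bf = 200.0 / (math.log(10.0) * 1000.0 * 10 ** (-5.514))
            d = np.empty(12)
            d[0] = JH * Surf / Vout
            d[1] = -JH * Surf / (Vin * Bf)
            d[2] = JK * Surf / Vout
            d[3] = -JK * Surf / Vin
            d[4] = JNa * Surf / Vout
            d[5] = -JNa * Surf / Vin
            d[6] = JCl * Surf / Vout
            d[7] = -JCl * Surf / Vin
            d[8] = -(2 * F / Cm) * (JH + JK + JNa - JCl)
            d[9] = 10.0 - (10.0 / 2.5) * atp
            d[10] = 1.05e-6 - (1.05e-6 / 0.562) * LHH
            d[11] = 1.08e-6 - (1.08e-6 / 0.579) * LHAr
            return d

        got = cf.rhs(5.0, y, p2a.model(glucose_active=True))
        assert np.allclose(got, oracle(y), rtol=1e-10)

    def test_entropy_production_nonnegative_under_psd_matrix(self, geom):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(5, 5)) * 1e-4
        Lpsd = A @ A.T  # positive semidefinite by construction
        entries = {}
        names = ("H", "K", "Na", "Cl", "Ar")
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i <= j:
                    entries[(a, b)] = float(Lpsd[i, j])
        matrix = CoefficientMatrix(entries)
        assert matrix.is_psd(tol=1e-18)
        atp = ATPParams(c_atp_eq=0.3, k_eq=0.1, atp_stimulus=2.5, k_atp_incr=1.0)
        model = Model(geom, matrix, atp, bf=100.0)
        for _ in range(25):
            vals = {f"{ion}_{side}": rng.uniform(1e-3, 100.0)
                    for ion in ("H", "K", "Na", "Cl") for side in ("in", "out")}
            vals["dphi"] = rng.uniform(-0.25, 0.25)
            vals["ATP"] = rng.uniform(0.01, 3.0)
            state = _state_for(matrix, vals, geom)
            assert cf.entropy_production(state, model) >= -1e-18


# ---------------------------------------------------------------------------
# geometry & pH helpers
# ---------------------------------------------------------------------------

class TestGeometry:
    def test_monolayer_surface_and_volume(self):
        g = Geometry.from_cell_monolayer()
        assert g.surf == pytest.approx(2.29e-5, rel=5e-3)
        assert g.v_in == pytest.approx(1.8e-11, rel=1e-9)

    def test_rejects_nonpositive_dimensions(self):
        with pytest.raises(ConfigurationError):
            Geometry(surf=0.0, v_in=1e-11, v_out=1e-6)

    def test_ph_conversion_round_trip(self):
        c = cf.ph_to_concentration_mM(5.5)
        assert cf.concentration_mM_to_ph(c) == pytest.approx(5.5, abs=1e-12)

    def test_buffering_factor_matches_definition(self):
        c_h = cf.ph_to_concentration_mM(5.514)
        bf = buffering_factor(200.0, c_h)
        assert bf == pytest.approx(200.0 / (math.log(10) * c_h), rel=1e-12)


class TestLiveMatrix:
    def test_dynamic_values_are_injected_symmetrically(self, p2a):
        model = p2a.model()
        L = live_matrix(model, np.array([7e-7, 3e-6]))
        assert L[0, 0] == 7e-7  # L_HH
        assert L[0, 4] == L[4, 0] == 3e-6  # L_HAr
        assert np.allclose(L, L.T)
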