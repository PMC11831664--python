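"""Unit and property tests for the equation-of-state layer."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq, minimize_scalar

from ldpmc import (
    MieParameters,
    VdwEoS,
    a_assoc,
    a_mono,
    assoc_delta,
    association_fraction,
    bh_diameter,
    chemical_potential,
    compressibility_from_eos,
    list_models,
    load_model,
    mie_potential,
    pressure_from_eos,
)
from ldpmc.eos import TemperatureDependentMie, a_excess, mie_prefactor, vdw_a_excess
from ldpmc.eos.association import AssociationParameters

WATER_MIE = MieParameters(epsilon=266.68, sigma=0.30063, lambda_r=17.02, lambda_a=6.0)


# ---------------------------------------------------------------- Mie potential
class TestMiePotential:
    def test_minimum_depth_and_location(self):
        # phi has a single minimum of depth -epsilon at r_min = (lr/la)^(1/(lr-la)) sigma
        res = minimize_scalar(
            lambda r: mie_potential(r, WATER_MIE), bounds=(0.2, 0.8), method="bounded"
        )
        r_min = (17.02 / 6.0) ** (1.0 / (17.02 - 6.0)) * WATER_MIE.sigma
        assert res.x == pytest.approx(r_min, rel=1e-5)
        assert res.fun == pytest.approx(-WATER_MIE.epsilon, rel=1e-8)

    def test_zero_crossing_at_sigma(self):
        assert mie_potential(WATER_MIE.sigma, WATER_MIE) == pytest.approx(0.0, abs=1e-9)

    def test_lj_prefactor(self):
        assert mie_prefactor(12.0, 6.0) == pytest.approx(4.0)

    def test_invalid_separation(self):
        with pytest.raises(ValueError):
            mie_potential(0.0, WATER_MIE)

    def test_invalid_exponents(self):
        with pytest.raises(ValueError):
            MieParameters(epsilon=100.0, sigma=0.3, lambda_r=6.0, lambda_a=12.0)
        with pytest.raises(ValueError):
            MieParameters(epsilon=100.0, sigma=0.3, lambda_r=12.0, lambda_a=2.0)

    @given(st.floats(min_value=0.31, max_value=3.0))
    def test_attractive_beyond_minimum_range(self, r):
        assert mie_potential(r, WATER_MIE) < 0.5


class TestTemperatureDependentMie:
    def test_constant_coefficients(self):
        tdep = TemperatureDependentMie(
            epsilon_coeffs=(300.0,),
            sigma_coeffs=(0.31,),
            lambda_r=12.0,
            lambda_a=6.0,
            t_range=(250.0, 600.0),
        )
        p = tdep.at(400.0)
        assert p.epsilon == 300.0 and p.sigma == 0.31

    def test_out_of_range_raises(self):
        tdep = TemperatureDependentMie(
            epsilon_coeffs=(300.0,),
            sigma_coeffs=(0.31,),
            lambda_r=12.0,
            lambda_a=6.0,
            t_range=(250.0, 600.0),
        )
        with pytest.raises(ValueError):
            tdep.at(700.0)


# ---------------------------------------------------------------- monomer term
class TestMonomer:
    def test_bh_diameter_quadrature_oracle(self):
        # Compare the fixed-order Gauss-Legendre result with adaptive quadrature.
        d = bh_diameter(400.0, WATER_MIE)
        # below sigma/2 the repulsion is thousands of k_B T: integrand is exactly 1
        tail, _ = quad(
            lambda r: 1.0 - np.exp(-min(mie_potential(r, WATER_MIE) / 400.0, 700.0)),
            0.5 * WATER_MIE.sigma,
            WATER_MIE.sigma,
            limit=200,
        )
        assert d == pytest.approx(0.5 * WATER_MIE.sigma + tail, rel=1e-8)

    def test_bh_diameter_bounds_and_monotonicity(self):
        d1 = bh_diameter(300.0, WATER_MIE)
        d2 = bh_diameter(600.0, WATER_MIE)
        assert 0.0 < d2 < d1 < WATER_MIE.sigma

    def test_hard_sphere_high_temperature_limit(self):
        # As T -> inf with fixed rho the excess free energy approaches T*a_HS(eta(d)).
        T = 1e8
        rho = 5.0
        d = bh_diameter(T, WATER_MIE)
        eta = np.pi / 6.0 * rho * d**3
        a_hs = (4.0 * eta - 3.0 * eta**2) / (1.0 - eta) ** 2
        assert a_mono(rho, T, WATER_MIE) / T == pytest.approx(a_hs, rel=1e-3)

    def test_zero_density_limit(self):
        assert a_mono(1e-14, 500.0, WATER_MIE) == pytest.approx(0.0, abs=1e-8)

    def test_packing_limit_raises(self):
        with pytest.raises(ValueError):
            a_mono(200.0, 300.0, WATER_MIE)

    @given(st.floats(min_value=0.5, max_value=30.0), st.floats(min_value=280.0, max_value=900.0))
    def test_finite_and_attractive_dominated_at_low_t(self, rho, T):
        val = a_mono(rho, T, WATER_MIE)
        assert np.isfinite(val)


# ------------------------------------------------------------------ association
class TestAssociation:
    def test_closed_form_half(self):
        # X(rho*Delta = 1) solves X = 1/(1+2X): X = 0.5
        assert association_fraction(1.0) == pytest.approx(0.5, abs=1e-12)

    def test_limits(self):
        assert association_fraction(0.0) == pytest.approx(1.0)
        assert association_fraction(1e12) == pytest.approx(0.0, abs=1e-5)

    @given(st.floats(min_value=0.0, max_value=1e8))
    def test_mass_action_residual(self, rho_delta):
        x = association_fraction(rho_delta)
        assert 0.0 < x <= 1.0
        assert x * (1.0 + 2.0 * rho_delta * x) == pytest.approx(1.0, rel=1e-9)

    def test_a_assoc_vanishes_without_bonding(self):
        weak = AssociationParameters(epsilon_assoc=1e-10, bond_volume=1e-3)
        assert a_assoc(20.0, 300.0, weak, WATER_MIE) == pytest.approx(0.0, abs=1e-8)

    def test_a_assoc_negative_when_bonding(self):
        strong = AssociationParameters(epsilon_assoc=1800.0, bond_volume=1.4e-3)
        assert a_assoc(30.0, 300.0, strong, WATER_MIE) < 0.0

    def test_delta_increases_with_density(self):
        p = AssociationParameters(epsilon_assoc=1800.0, bond_volume=1.4e-3)
        assert assoc_delta(30.0, 300.0, p, WATER_MIE) > assoc_delta(1.0, 300.0, p, WATER_MIE)

    def test_four_sites_enforced(self):
        with pytest.raises(ValueError):
            AssociationParameters(epsilon_assoc=1800.0, bond_volume=1.4e-3, n_h=3)


# ----------------------------------------------------------------------- models
class TestModels:
    def test_vdw_closed_form(self, vdw_model):
        rho, T = 12.0, 500.0
        expected = -T * np.log1p(-vdw_model.b * rho) - vdw_model.a * rho
        assert vdw_model.a_excess(rho, T) == pytest.approx(expected, rel=1e-12)
        assert vdw_a_excess(rho, T, vdw_model.a, vdw_model.b) == pytest.approx(expected)

    def test_vdw_pressure_closed_form(self, vdw_model):
        rho, T = 12.0, 500.0
        expected = rho * T / (1.0 - vdw_model.b * rho) - vdw_model.a * rho**2
        assert pressure_from_eos(rho, T, vdw_model) == pytest.approx(expected, rel=1e-9)

    def test_pressure_thermodynamic_identity(self, assoc_model):
        # p = rho T + rho^2 da/drho must hold with the numeric derivative
        rho, T = 30.0, 400.0
        h = 1e-5 * rho
        da = (assoc_model.a_excess(rho + h, T) - assoc_model.a_excess(rho - h, T)) / (2 * h)
        p = pressure_from_eos(rho, T, assoc_model)
        assert p == pytest.approx(rho * T + rho**2 * da, rel=1e-5)

    def test_chemical_potential_identity(self, vdw_model):
        # mu = a_ideal' + (rho a_ex)' = T ln rho + a_ex + rho a_ex'
        rho, T = 8.0, 600.0
        mu = chemical_potential(rho, T, vdw_model)
        expected = (
            T * np.log(rho)
            + vdw_model.a_excess(rho, T)
            + rho * (T * vdw_model.b / (1 - vdw_model.b * rho) - vdw_model.a)
        )
        assert mu == pytest.approx(expected, rel=1e-9)

    def test_gibbs_duhem_consistency(self, vdw_model):
        # rho dmu/drho = dp/drho at constant T
        rho, T = 9.0, 700.0
        h = 1e-6 * rho
        dmu = (chemical_potential(rho + h, T, vdw_model) - chemical_potential(rho - h, T, vdw_model)) / (2 * h)
        dp = (pressure_from_eos(rho + h, T, vdw_model) - pressure_from_eos(rho - h, T, vdw_model)) / (2 * h)
        assert rho * dmu == pytest.approx(dp, rel=1e-5)

    def test_ideal_model(self, ideal_model):
        assert ideal_model.a_excess(5.0, 300.0) == 0.0
        assert pressure_from_eos(5.0, 300.0, ideal_model) == pytest.approx(1500.0)
        assert compressibility_from_eos(5.0, 300.0, ideal_model) == pytest.approx(1.0 / 1500.0)

    def test_compressibility_positive_stable(self, vdw_model):
        assert compressibility_from_eos(2.0, 700.0, vdw_model) > 0.0

    def test_compressibility_unstable_raises(self, vdw_model):
        # inside the spinodal at low T the derivative is negative
        with pytest.raises(ValueError):
            compressibility_from_eos(10.0, 450.0, vdw_model)

    def test_registry(self):
        names = list_models()
        assert {"vdw", "ideal", "associating"}.issubset(names)
        with pytest.raises(ValueError):
            load_model("no-such-model")

    def test_a_excess_helper_matches_method(self, assoc_model):
        assert a_excess(20.0, 350.0, assoc_model) == pytest.approx(
            assoc_model.a_excess(20.0, 350.0)
        )

    def test_vdw_critical_point(self, vdw_model):
        tc = vdw_model.critical_temperature
        rc = vdw_model.critical_density
        # dp/drho = d2p/drho2 = 0 at the critical point
        h = 1e-4 * rc
        p = lambda r: pressure_from_eos(r, tc, vdw_model)
        d1 = (p(rc + h) - p(rc - h)) / (2 * h)
        d2 = (p(rc + h) - 2 * p(rc) + p(rc - h)) / h**2
        assert abs(d1) < 1e-3 * p(rc) / rc
        assert abs(d2) < 1e-2 * p(rc) / rc**2
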