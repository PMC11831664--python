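"""Kernel, field and energy tests against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from ldpmc import (
    Configuration,
    IdealEoS,
    PotentialSpec,
    VdwEoS,
    build_lookup_table,
    compute_local_densities,
    delta_energy_move,
    lucy_weight,
    lucy_weight_gradient,
    total_energy,
)


def brute_force_field(pos, box, rc):
    """Independent double-loop implementation of the weighted density field."""
    n = len(pos)
    rho = np.zeros(n)
    grad = np.zeros((n, 3))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pos[i] - pos[j]  # vector from j to i
            d -= box * np.rint(d / box)
            r = np.linalg.norm(d)
            if r < rc:
                rho[i] += lucy_weight(r, rc)
                if r > 0:
                    grad[i] += lucy_weight_gradient(r, rc) * d / r
    return rho, grad


def brute_force_energy(pos, box, spec):
    rho, grad = brute_force_field(pos, box, spec.r_c)
    u = float(np.sum([spec.eos.a_excess(max(r, 0.0), spec.T) for r in rho]))
    u += 0.5 * spec.kappa * float(np.sum(grad**2))
    return u


# ------------------------------------------------------------------ Lucy kernel
class TestLucyKernel:
    @pytest.mark.parametrize("rc", [0.5, 1.0, 2.7])
    def test_normalization(self, rc):
        val, _ = quad(lambda r: 4 * np.pi * r**2 * lucy_weight(r, rc), 0, rc, limit=200)
        assert abs(val - 1.0) <= 1e-10

    def test_compact_support(self):
        assert lucy_weight(1.0, 1.0) == 0.0
        assert lucy_weight(3.0, 1.0) == 0.0
        assert lucy_weight_gradient(1.0, 1.0) == 0.0

    def test_continuity_at_cutoff(self):
        eps = 1e-8
        assert lucy_weight(1.0 - eps, 1.0) == pytest.approx(0.0, abs=1e-20)
        assert lucy_weight_gradient(1.0 - eps, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_gradient_is_derivative(self):
        rc, h = 1.3, 1e-7
        for r in [0.2, 0.5, 0.9, 1.1]:
            num = (lucy_weight(r + h, rc) - lucy_weight(r - h, rc)) / (2 * h)
            assert lucy_weight_gradient(r, rc) == pytest.approx(num, abs=1e-4)

    def test_maximum_at_origin(self):
        rc = 1.0
        assert lucy_weight(0.0, rc) == pytest.approx(105.0 / (16.0 * np.pi))
        assert lucy_weight_gradient(0.0, rc) == 0.0

    @given(st.floats(min_value=0.0, max_value=2.0), st.floats(min_value=0.3, max_value=3.0))
    def test_non_negative(self, r, rc):
        assert lucy_weight(r, rc) >= 0.0


# ------------------------------------------------------------------ field/energy
class TestFieldOracle:
    def test_field_matches_brute_force(self, small_config):
        rc = 1.1
        field = compute_local_densities(small_config, rc)
        rho_ref, grad_ref = brute_force_field(small_config.positions, small_config.box, rc)
        np.testing.assert_allclose(field.rho_bar, rho_ref, rtol=1e-12, atol=1e-12)
        np.testing.assert_allclose(field.grad_rho, grad_ref, rtol=1e-12, atol=1e-10)

    def test_self_term_excluded(self):
        cfg = Configuration(np.array([[2.0, 2.0, 2.0]]), np.array([4.0, 4.0, 4.0]))
        field = compute_local_densities(cfg, 1.0)
        assert field.rho_bar[0] == 0.0
        assert np.all(field.grad_rho[0] == 0.0)

    def test_two_particle_pairwise_values(self):
        rc, sep = 1.5, 0.6
        cfg = Configuration(
            np.array([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0 + sep]]), np.array([6.0, 6.0, 6.0])
        )
        field = compute_local_densities(cfg, rc)
        w = lucy_weight(sep, rc)
        assert field.rho_bar == pytest.approx([w, w])
        dw = lucy_weight_gradient(sep, rc)
        # gradient of particle 0 points away from particle 1 (down the z axis)
        assert field.grad_rho[0, 2] == pytest.approx(-dw)
        assert field.grad_rho[1, 2] == pytest.approx(dw)

    def test_energy_matches_brute_force_vdw(self, small_config, vdw_model):
        spec = PotentialSpec(eos=vdw_model, T=500.0, r_c=1.1, kappa=0.3)
        u = total_energy(small_config, spec)
        u_ref = brute_force_energy(small_config.positions, small_config.box, spec)
        assert u == pytest.approx(u_ref, rel=1e-9)

    def test_energy_zero_for_ideal(self, small_config, ideal_model):
        spec = PotentialSpec(eos=ideal_model, T=500.0, r_c=1.1)
        assert total_energy(small_config, spec) == 0.0

    def test_translation_invariance(self, small_config, vdw_model):
        spec = PotentialSpec(eos=vdw_model, T=500.0, r_c=1.1, kappa=0.2)
        u0 = total_energy(small_config, spec)
        shifted = Configuration(
            small_config.positions + np.array([0.37, -1.2, 2.9]), small_config.box
        )
        assert total_energy(shifted, spec) == pytest.approx(u0, rel=1e-10)

    def test_permutation_invariance(self, small_config, vdw_model, rng):
        spec = PotentialSpec(eos=vdw_model, T=500.0, r_c=1.1, kappa=0.2)
        u0 = total_energy(small_config, spec)
        perm = rng.permutation(small_config.n_particles)
        permuted = Configuration(small_config.positions[perm], small_config.box)
        assert total_energy(permuted, spec) == pytest.approx(u0, rel=1e-12)

    def test_box_too_small_raises(self, vdw_model):
        cfg = Configuration(np.array([[0.5, 0.5, 0.5]]), np.array([1.0, 1.0, 1.0]))
        with pytest.raises(ValueError):
            compute_local_densities(cfg, 0.9)


class TestDeltaEnergy:
    def test_matches_full_recomputation(self, small_config, vdw_model, rng):
        spec = PotentialSpec(eos=vdw_model, T=500.0, r_c=1.1, kappa=0.25)
        field = compute_local_densities(small_config, spec.r_c)
        u0 = total_energy(small_config, spec, field)
        for _ in range(25):
            i = int(rng.integers(small_config.n_particles))
            new = (small_config.positions[i] + rng.normal(0, 0.5, 3)) % small_config.box
            du = delta_energy_move(small_config, field, i, new, spec)
            moved = small_config.copy()
            moved.positions[i] = new
            u1 = total_energy(moved, spec)
            assert du == pytest.approx(u1 - u0, rel=1e-9, abs=1e-9)

    def test_null_move_zero(self, small_config, vdw_model):
        spec = PotentialSpec(eos=vdw_model, T=500.0, r_c=1.1)
        field = compute_local_densities(small_config, spec.r_c)
        du = delta_energy_move(small_config, field, 3, small_config.positions[3], spec)
        assert du == pytest.approx(0.0, abs=1e-10)


# ------------------------------------------------------------------- lookup table
class TestLookupTable:
    def test_spline_accuracy(self, vdw_model):
        table = build_lookup_table(vdw_model, T=500.0, rho_max=30.0, n_points=2001)
        rho = np.linspace(0.0, 30.0, 777)
        exact = vdw_model.a_excess(rho, 500.0)
        approx = table(rho)
        assert np.max(np.abs(approx - exact)) < 1e-6 * max(1.0, np.max(np.abs(exact)))

    def test_starts_at_zero_density(self, vdw_model):
        table = build_lookup_table(vdw_model, T=500.0, rho_max=30.0, n_points=501)
        assert table(0.0) == pytest.approx(0.0, abs=1e-10)

    def test_too_few_points_raises(self, vdw_model):
        with pytest.raises(ValueError):
            build_lookup_table(vdw_model, T=500.0, rho_max=30.0, n_points=4)

    def test_kernel_linear_extrapolation(self, vdw_model):
        # beyond the tabulated range the engine-side evaluation continues
        # linearly, so it must stay monotonically increasing (no spurious well)
        from ldpmc._kernels import _spline_eval

        table = build_lookup_table(vdw_model, T=500.0, rho_max=25.0, n_points=501)
        m = table.coeffs.shape[1]
        vals = [_spline_eval(x, table.dx, table.coeffs, m) for x in np.linspace(25.0, 80.0, 40)]
        assert np.all(np.diff(vals) > 0)

    def test_for_model_cutoff_convention(self, vdw_model):
        spec = PotentialSpec.for_model(vdw_model, 500.0)
        assert spec.r_c == pytest.approx(4.0 * vdw_model.sigma_equivalent())
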