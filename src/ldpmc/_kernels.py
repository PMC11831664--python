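"""Numba kernels for local-density fields and Metropolis sweeps.

These are internal: all public entry points live in :mod:`ldpmc.ldp_core`
and :mod:`ldpmc.mc_engine`.  The kernels keep the per-particle weighted
densities and their gradients as mutable state and update them
incrementally during particle moves; the excess free energy is evaluated
from a piecewise-cubic lookup table (uniform density grid, scipy
CubicSpline coefficient layout).

Conventions: positions wrapped into [0, L), minimum-image distances,
energies in kelvin (k_B = 1), beta = 1/T.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_PI = np.pi


@njit(cache=False, inline="always")
def _lucy(r, rc):
    """Lucy weight, 3-D normalized; 0 for r >= rc."""
    if r >= rc:
        return 0.0
    x = r / rc
    a = 105.0 / (16.0 * _PI * rc**3)
    return a * (1.0 + 3.0 * x) * (1.0 - x) ** 3


@njit(cache=False, inline="always")
def _dlucy(r, rc):
    """Radial derivative dw/dr of the Lucy weight; 0 at r = 0 and r >= rc."""
    if r >= rc:
        return 0.0
    x = r / rc
    a = 105.0 / (16.0 * _PI * rc**3)
    return -12.0 * a * x * (1.0 - x) ** 2 / rc


@njit(cache=False, inline="always")
def _spline_eval(x, dx_grid, coeffs, n_intervals):
    """Piecewise cubic a_ex(x).

    Beyond the tabulated range the value continues *linearly* with the end
    slope: a cubic extrapolation can turn over and produce a spurious
    attractive well at high density, which would let the system collapse.
    """
    if x >= n_intervals * dx_grid:
        i = n_intervals - 1
        t_end = dx_grid
        y_end = ((coeffs[0, i] * t_end + coeffs[1, i]) * t_end + coeffs[2, i]) * t_end + coeffs[3, i]
        slope = (3.0 * coeffs[0, i] * t_end + 2.0 * coeffs[1, i]) * t_end + coeffs[2, i]
        return y_end + slope * (x - n_intervals * dx_grid)
    i = int(x / dx_grid)
    if i < 0:
        i = 0
    t = x - i * dx_grid
    return ((coeffs[0, i] * t + coeffs[1, i]) * t + coeffs[2, i]) * t + coeffs[3, i]


@njit(cache=False)
def field_kernel(pos, box, rc):
    """Weighted densities and their gradients, brute-force O(N^2).

    Returns (rho_bar, grad_rho); the self term is excluded, so a particle
    with no neighbors inside rc has rho_bar = 0.
    """
    n = pos.shape[0]
    rho = np.zeros(n)
    grad = np.zeros((n, 3))
    lx, ly, lz = box[0], box[1], box[2]
    rc2 = rc * rc
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            dx -= lx * np.rint(dx / lx)
            dy -= ly * np.rint(dy / ly)
            dz -= lz * np.rint(dz / lz)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc2:
                continue
            r = np.sqrt(r2)
            w = _lucy(r, rc)
            rho[i] += w
            rho[j] += w
            if r > 1e-12:
                inv = _dlucy(r, rc) / r
                # grad_i gets unit vector from j to i = -(dx,dy,dz)/r
                grad[i, 0] -= inv * dx
                grad[i, 1] -= inv * dy
                grad[i, 2] -= inv * dz
                grad[j, 0] += inv * dx
                grad[j, 1] += inv * dy
                grad[j, 2] += inv * dz
    return rho, grad


@njit(cache=False)
def spline_energy(rho, grad, coeffs, dx_grid, kappa, rho_table_max):
    """U = sum_i a_ex(rho_i) + (kappa/2) sum_i |grad_i|^2 from the lookup.

    Returns (U, n_out_of_range) where the counter flags densities beyond the
    tabulated interval (continued linearly with the end slope).
    """
    n = rho.shape[0]
    m = coeffs.shape[1]
    u = 0.0
    n_out = 0
    for i in range(n):
        if rho[i] > rho_table_max:
            n_out += 1
        u += _spline_eval(rho[i], dx_grid, coeffs, m)
        if kappa != 0.0:
            u += 0.5 * kappa * (
                grad[i, 0] ** 2 + grad[i, 1] ** 2 + grad[i, 2] ** 2
            )
    return u, n_out


@njit(cache=False)
def sweep_kernel(
    pos,
    box,
    rho,
    grad,
    coeffs,
    dx_grid,
    rho_table_max,
    rc,
    kappa,
    beta,
    max_disp,
    n_cycles,
    rng,
):
    """``n_cycles`` Metropolis cycles of single-particle displacements.

    A cycle is N attempted displacements, particles visited in index order.
    Mutates pos/rho/grad in place; returns (accumulated dU, accepted count,
    attempted count, out-of-table events).
    """
    n = pos.shape[0]
    lx, ly, lz = box[0], box[1], box[2]
    rc2 = rc * rc
    m = coeffs.shape[1]
    drho = np.empty(n)
    gnew = np.empty((n, 3))
    touched = np.empty(n, dtype=np.int64)
    du_total = 0.0
    n_acc = 0
    n_out = 0
    for _ in range(n_cycles):
        for i in range(n):
            nxx = pos[i, 0] + (2.0 * rng.random() - 1.0) * max_disp
            nyy = pos[i, 1] + (2.0 * rng.random() - 1.0) * max_disp
            nzz = pos[i, 2] + (2.0 * rng.random() - 1.0) * max_disp
            nxx -= lx * np.floor(nxx / lx)
            nyy -= ly * np.floor(nyy / ly)
            nzz -= lz * np.floor(nzz / lz)

            du = 0.0
            rho_i_new = 0.0
            gix = 0.0
            giy = 0.0
            giz = 0.0
            n_touch = 0
            for j in range(n):
                if j == i:
                    continue
                dxo = pos[j, 0] - pos[i, 0]
                dyo = pos[j, 1] - pos[i, 1]
                dzo = pos[j, 2] - pos[i, 2]
                dxo -= lx * np.rint(dxo / lx)
                dyo -= ly * np.rint(dyo / ly)
                dzo -= lz * np.rint(dzo / lz)
                r2o = dxo * dxo + dyo * dyo + dzo * dzo
                dxn = pos[j, 0] - nxx
                dyn = pos[j, 1] - nyy
                dzn = pos[j, 2] - nzz
                dxn -= lx * np.rint(dxn / lx)
                dyn -= ly * np.rint(dyn / ly)
                dzn -= lz * np.rint(dzn / lz)
                r2n = dxn * dxn + dyn * dyn + dzn * dzn
                in_old = r2o < rc2
                in_new = r2n < rc2
                if not in_old and not in_new:
                    continue
                gjx = grad[j, 0]
                gjy = grad[j, 1]
                gjz = grad[j, 2]
                d = 0.0
                if in_old:
                    ro = np.sqrt(r2o)
                    d -= _lucy(ro, rc)
                    if ro > 1e-12:
                        inv = _dlucy(ro, rc) / ro
                        gjx -= inv * dxo
                        gjy -= inv * dyo
                        gjz -= inv * dzo
                if in_new:
                    rn = np.sqrt(r2n)
                    wn = _lucy(rn, rc)
                    d += wn
                    rho_i_new += wn
                    if rn > 1e-12:
                        inv = _dlucy(rn, rc) / rn
                        # grad_j gains contribution along (r_j - r_i_new)
                        gjx += inv * dxn
                        gjy += inv * dyn
                        gjz += inv * dzn
                        # grad_i gains contribution along (r_i_new - r_j)
                        gix -= inv * dxn
                        giy -= inv * dyn
                        giz -= inv * dzn
                rj_new = rho[j] + d
                if rj_new > rho_table_max:
                    n_out += 1
                du += _spline_eval(rj_new, dx_grid, coeffs, m) - _spline_eval(
                    rho[j], dx_grid, coeffs, m
                )
                if kappa != 0.0:
                    du += 0.5 * kappa * (
                        gjx * gjx
                        + gjy * gjy
                        + gjz * gjz
                        - grad[j, 0] ** 2
                        - grad[j, 1] ** 2
                        - grad[j, 2] ** 2
                    )
                drho[j] = d
                gnew[j, 0] = gjx
                gnew[j, 1] = gjy
                gnew[j, 2] = gjz
                touched[n_touch] = j
                n_touch += 1

            if rho_i_new > rho_table_max:
                n_out += 1
            du += _spline_eval(rho_i_new, dx_grid, coeffs, m) - _spline_eval(
                rho[i], dx_grid, coeffs, m
            )
            if kappa != 0.0:
                du += 0.5 * kappa * (
                    gix * gix
                    + giy * giy
                    + giz * giz
                    - grad[i, 0] ** 2
                    - grad[i, 1] ** 2
                    - grad[i, 2] ** 2
                )

            accept = False
            if du <= 0.0:
                accept = True
            elif rng.random() < np.exp(-beta * du):
                accept = True
            if accept:
                pos[i, 0] = nxx
                pos[i, 1] = nyy
                pos[i, 2] = nzz
                rho[i] = rho_i_new
                grad[i, 0] = gix
                grad[i, 1] = giy
                grad[i, 2] = giz
                for k in range(n_touch):
                    j = touched[k]
                    rho[j] += drho[j]
                    grad[j, 0] = gnew[j, 0]
                    grad[j, 1] = gnew[j, 1]
                    grad[j, 2] = gnew[j, 2]
                du_total += du
                n_acc += 1
    return du_total, n_acc, n_cycles * n, n_out
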