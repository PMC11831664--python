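"""Monomer (segment) contribution to the SAFT-VR Mie excess free energy.

This is the high-temperature Barker-Henderson perturbation expansion about a
hard-sphere reference, truncated at third order:

    a_mono / (k_B T) = a_HS + beta a_1 + beta^2 a_2 + beta^3 a_3,

with the hard-sphere diameter d(T) obtained from the Barker-Henderson
integral of the Mie potential, the Carnahan-Starling hard-sphere term, and
the a_1, a_2, a_3 terms expressed through the correlation-integral
approximations of the variable-range Mie formulation (mean-value theorem
with an effective packing fraction, plus the fluctuation correction K_HS
(1 + chi) at second order and a fitted third-order term).

All public functions use k_B = 1 (energies in kelvin) and densities in
nm^-3; they are vectorized over density.
"""

from __future__ import annotations

import numpy as np

from .mie import MieParameters, mie_prefactor, mie_potential

__all__ = ["bh_diameter", "a_mono", "packing_fraction"]

#: close-packing bound used as the domain limit for the hard-sphere reference
ETA_MAX = 0.74048

# Coefficient matrix mapping (1, 1/lam, 1/lam^2, 1/lam^3) -> (c1..c4) for the
# effective packing fraction of the mean-value-theorem correlation integral.
_C_ETA_EFF = np.array(
    [
        [0.81096, 1.7888, -37.578, 92.284],
        [1.0205, -19.341, 151.26, -463.50],
        [-1.9057, 22.845, -228.14, 973.92],
        [1.0885, -6.1962, 106.98, -677.64],
    ]
)

# phi_{k,n} coefficients of the rational functions f_k(alpha), k = 1..6,
# used in the second-order fluctuation correction and the third-order term.
_PHI = np.array(
    [
        [7.5365557, -37.60463, 71.745953, -46.83552, -2.467982, -0.50272, 8.0956883],
        [-359.44, 1825.6, -3168.0, 1884.2, -0.82376, -3.1935, 3.7090],
        [1550.9, -5070.1, 6534.6, -3288.7, -2.7171, 2.0883, 0.0],
        [-1.19932, 9.063632, -17.9482, 11.34027, 20.52142, -56.6377, 40.53683],
        [-1911.28, 21390.175, -51320.7, 37064.54, 1103.742, -3264.61, 2556.181],
        [9236.9, -129430.0, 357230.0, -315530.0, 1390.2, -4518.2, 4241.6],
    ]
)

# Gauss-Legendre nodes/weights on [0, 1] for the Barker-Henderson integral.
_GL_X, _GL_W = np.polynomial.legendre.leggauss(64)
_GL_X = 0.5 * (_GL_X + 1.0)
_GL_W = 0.5 * _GL_W


def bh_diameter(T: float, p: MieParameters) -> float:
    """Barker-Henderson effective hard-sphere diameter d(T), in nm.

    d = int_0^sigma [1 - exp(-phi_Mie(r)/T)] dr, evaluated by 64-point
    Gauss-Legendre quadrature with overflow-safe exponentiation (the
    integrand is exactly 1 wherever the potential is many k_B T).
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    r = _GL_X * p.sigma
    beta_u = mie_potential(r, p) / T
    integrand = -np.expm1(-np.clip(beta_u, -np.inf, 700.0))
    return float(p.sigma * np.sum(_GL_W * integrand))


def packing_fraction(rho, d: float):
    """Packing fraction eta = (pi/6) rho d^3 for single-segment particles."""
    return np.pi / 6.0 * np.asarray(rho, dtype=float) * d**3


def _f_alpha(alpha: float) -> np.ndarray:
    """The six rational functions f_k(alpha) of the Mie dispersion parameter."""
    num = _PHI[:, 0] + _PHI[:, 1] * alpha + _PHI[:, 2] * alpha**2 + _PHI[:, 3] * alpha**3
    den = 1.0 + _PHI[:, 4] * alpha + _PHI[:, 5] * alpha**2 + _PHI[:, 6] * alpha**3
    return num / den


def _eta_eff(eta: np.ndarray, lam: float) -> np.ndarray:
    inv = np.array([1.0, 1.0 / lam, lam**-2, lam**-3])
    c1, c2, c3, c4 = _C_ETA_EFF @ inv
    return c1 * eta + c2 * eta**2 + c3 * eta**3 + c4 * eta**4


def _a1s(eta: np.ndarray, lam: float, eps: float) -> np.ndarray:
    ne = _eta_eff(eta, lam)
    return -12.0 * eps * eta / (lam - 3.0) * (1.0 - ne / 2.0) / (1.0 - ne) ** 3


def _b_term(eta: np.ndarray, lam: float, x0: float, eps: float) -> np.ndarray:
    i_l = (1.0 - x0 ** (3.0 - lam)) / (lam - 3.0)
    j_l = -(x0 ** (4.0 - lam) * (lam - 3.0) - x0 ** (3.0 - lam) * (lam - 4.0) - 1.0) / (
        (lam - 3.0) * (lam - 4.0)
    )
    one = (1.0 - eta / 2.0) / (1.0 - eta) ** 3
    two = 9.0 * eta * (1.0 + eta) / (2.0 * (1.0 - eta) ** 3)
    return 12.0 * eps * eta * (one * i_l - two * j_l)


def _a1s_plus_b(eta, lam, x0, eps):
    return _a1s(eta, lam, eps) + _b_term(eta, lam, x0, eps)


def a_mono(rho, T: float, p: MieParameters):
    """Monomer excess Helmholtz free energy per particle, in kelvin.

    Parameters
    ----------
    rho : float or ndarray
        Number density, nm^-3; must lie below the packing limit of the
        effective hard-sphere diameter.
    T : float
        Temperature, kelvin.
    p : MieParameters

    Returns
    -------
    float or ndarray
        a_mono(rho, T) with a_mono(0, T) = 0.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("density must be non-negative")
    d = bh_diameter(T, p)
    eta = packing_fraction(rho, d)
    if np.any(eta >= ETA_MAX):
        raise ValueError(
            f"packing fraction {float(np.max(eta)):.4f} at or above the "
            f"hard-sphere packing limit {ETA_MAX} (d = {d:.4f} nm)"
        )
    x0 = p.sigma / d
    lr, la = p.lambda_r, p.lambda_a
    eps = p.epsilon
    c = mie_prefactor(lr, la)
    alpha = c * (1.0 / (la - 3.0) - 1.0 / (lr - 3.0))
    f1, f2, f3, f4, f5, f6 = _f_alpha(alpha)

    # hard-sphere reference (Carnahan-Starling), in units of k_B T
    a_hs = (4.0 * eta - 3.0 * eta**2) / (1.0 - eta) ** 2

    # first-order mean-attraction term, units of kelvin
    a1 = c * (x0**la * _a1s_plus_b(eta, la, x0, eps) - x0**lr * _a1s_plus_b(eta, lr, x0, eps))

    # second-order fluctuation term, units of kelvin^2
    zeta_x = eta * x0**3
    chi = f1 * zeta_x + f2 * zeta_x**5 + f3 * zeta_x**8
    k_hs = (1.0 - eta) ** 4 / (1.0 + 4.0 * eta + 4.0 * eta**2 - 4.0 * eta**3 + eta**4)
    a2 = (
        0.5
        * k_hs
        * (1.0 + chi)
        * eps
        * c**2
        * (
            x0 ** (2 * la) * _a1s_plus_b(eta, 2 * la, x0, eps)
            - 2.0 * x0 ** (la + lr) * _a1s_plus_b(eta, la + lr, x0, eps)
            + x0 ** (2 * lr) * _a1s_plus_b(eta, 2 * lr, x0, eps)
        )
    )

    # third-order empirical term, units of kelvin^3
    a3 = -(eps**3) * f4 * zeta_x * np.exp(f5 * zeta_x + f6 * zeta_x**2)

    out = T * a_hs + a1 + a2 / T + a3 / T**2
    return out if out.ndim else float(out)
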