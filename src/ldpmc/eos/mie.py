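"""Mie pair potential and its parameter containers.

The Mie potential is a generalized Lennard-Jones interaction with independent
repulsive and attractive exponents,

    phi(r) = C eps [ (sigma/r)^lr - (sigma/r)^la ],
    C      = lr/(lr - la) * (lr/la)^(la/(lr - la)),

where the prefactor C guarantees that the well depth equals eps.  In this
package the Mie potential never acts pairwise in a simulation; it only
parametrizes the underlying equation of state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MieParameters",
    "TemperatureDependentMie",
    "mie_prefactor",
    "mie_potential",
]


@dataclass(frozen=True)
class MieParameters:
    """Parameters of a Mie (lambda_r, lambda_a) interaction.

    Attributes
    ----------
    epsilon : float
        Well depth expressed as eps/k_B, in kelvin.
    sigma : float
        Size parameter, in nanometers.
    lambda_r, lambda_a : float
        Repulsive and attractive exponents. ``lambda_r > lambda_a > 3`` is
        required so the attractive tail is integrable in 3-D.
    """

    epsilon: float
    sigma: float
    lambda_r: float
    lambda_a: float

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not (self.lambda_r > self.lambda_a > 3):
            raise ValueError(
                "exponents must satisfy lambda_r > lambda_a > 3, got "
                f"lambda_r={self.lambda_r}, lambda_a={self.lambda_a}"
            )


@dataclass(frozen=True)
class TemperatureDependentMie:
    """Mie parameters whose eps and sigma are polynomials in temperature.

    ``epsilon_coeffs`` and ``sigma_coeffs`` hold polynomial coefficients in
    ascending order (c0 + c1*T + c2*T^2 + ...), with T in kelvin, producing
    eps/k_B in kelvin and sigma in nm.  Evaluation outside ``t_range`` is an
    error: these parametrizations are fits with no physical meaning beyond
    their fitting window.
    """

    epsilon_coeffs: tuple[float, ...]
    sigma_coeffs: tuple[float, ...]
    lambda_r: float
    lambda_a: float
    t_range: tuple[float, float] = field(default=(0.0, np.inf))

    def at(self, T: float) -> MieParameters:
        """Evaluate the parameters at temperature ``T`` (kelvin)."""
        lo, hi = self.t_range
        if not (lo <= T <= hi):
            raise ValueError(
                f"temperature {T} K outside the parametrized interval [{lo}, {hi}] K"
            )
        eps = float(np.polynomial.polynomial.polyval(T, self.epsilon_coeffs))
        sig = float(np.polynomial.polynomial.polyval(T, self.sigma_coeffs))
        return MieParameters(eps, sig, self.lambda_r, self.lambda_a)


def mie_prefactor(lambda_r: float, lambda_a: float) -> float:
    """Analytic prefactor C that normalizes the Mie well depth to eps."""
    lr, la = lambda_r, lambda_a
    return lr / (lr - la) * (lr / la) ** (la / (lr - la))


def mie_potential(r, p: MieParameters):
    """Mie pair potential, in kelvin (eps/k_B convention).

    Parameters
    ----------
    r : float or ndarray
        Separation in nm; must be strictly positive.
    p : MieParameters

    Returns
    -------
    float or ndarray
        C eps [(sigma/r)^lr - (sigma/r)^la]; tends to 0 as r -> inf and to
        -eps at the minimum.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation r must be strictly positive")
    c = mie_prefactor(p.lambda_r, p.lambda_a)
    x = p.sigma / r
    out = c * p.epsilon * (x**p.lambda_r - x**p.lambda_a)
    return out if out.ndim else float(out)
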