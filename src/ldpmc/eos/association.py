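"""Wertheim (TPT1) association contribution for four-site water.

Water is given two hydrogen-type sites (H) and two lone-pair-type sites (e);
only H-e bonding is allowed.  By symmetry every site then has the same
fraction X of instances NOT bonded, and the mass-action equation

    X = 1 / (1 + 2 rho Delta X)

has the closed-form solution

    X = (-1 + sqrt(1 + 8 rho Delta)) / (4 rho Delta).

The free-energy contribution per particle (in units of k_B T) for the four
symmetric sites is  4 (ln X - X/2) + 2.

The association strength Delta(rho, T) is modelled with the first-order
thermodynamic-perturbation closure

    Delta = K_AB [exp(eps_HB / T) - 1] g_HS(d; eta),

where K_AB is the bonding volume (nm^3), eps_HB the association well depth
(kelvin) and g_HS the contact value of the hard-sphere pair distribution at
the Barker-Henderson diameter, g_HS = (1 - eta/2)/(1 - eta)^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mie import MieParameters
from .monomer import bh_diameter, packing_fraction

__all__ = ["AssociationParameters", "association_fraction", "assoc_delta", "a_assoc"]


@dataclass(frozen=True)
class AssociationParameters:
    """Four-site (2 H + 2 e) association parameters.

    epsilon_assoc is the association well depth as eps_HB/k_B in kelvin;
    bond_volume is the bonding volume K_AB in nm^3.
    """

    epsilon_assoc: float
    bond_volume: float
    n_h: int = 2
    n_e: int = 2

    def __post_init__(self) -> None:
        if self.n_h != 2 or self.n_e != 2:
            raise ValueError("only the symmetric 2 H + 2 e site model is supported")
        if self.epsilon_assoc < 0:
            raise ValueError("epsilon_assoc must be non-negative")
        if self.bond_volume < 0:
            raise ValueError("bond_volume must be non-negative")


def association_fraction(rho_delta):
    """Fraction X of sites not bonded, given the product rho*Delta.

    Closed-form root of the symmetric four-site mass-action equation
    X = 1/(1 + 2 rho Delta X); X -> 1 as rho*Delta -> 0 and X -> 0 as
    rho*Delta -> inf.
    """
    rd = np.asarray(rho_delta, dtype=float)
    if np.any(rd < 0):
        raise ValueError("rho*Delta must be non-negative")
    with np.errstate(invalid="ignore", divide="ignore"):
        x = (-1.0 + np.sqrt(1.0 + 8.0 * rd)) / (4.0 * rd)
    # series branch: the closed form cancels catastrophically for small rd
    x = np.where(rd < 1e-5, 1.0 - 2.0 * rd + 8.0 * rd * rd, x)
    return x if x.ndim else float(x)


def assoc_delta(rho, T: float, p: AssociationParameters, mie: MieParameters):
    """Association strength Delta(rho, T), in nm^3."""
    d = bh_diameter(T, mie)
    eta = packing_fraction(rho, d)
    g_contact = (1.0 - eta / 2.0) / (1.0 - eta) ** 3
    mayer_f = np.expm1(min(p.epsilon_assoc / T, 700.0))
    return p.bond_volume * mayer_f * g_contact


def a_assoc(rho, T: float, p: AssociationParameters, mie: MieParameters):
    """Association excess free energy per particle, in kelvin.

    Equals T * [4 (ln X - X/2) + 2]; vanishes when epsilon_assoc -> 0 or
    rho -> 0 (X -> 1).
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("density must be non-negative")
    if p.epsilon_assoc == 0.0 or p.bond_volume == 0.0:
        out = np.zeros_like(rho)
        return out if out.ndim else 0.0
    delta = assoc_delta(rho, T, p, mie)
    x = association_fraction(rho * delta)
    out = T * (4.0 * (np.log(x) - x / 2.0) + 2.0)
    return out if out.ndim else float(out)
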