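"""Unit conventions and conversion constants.

Internally the package works in a reduced unit system chosen to keep Monte
Carlo acceptance ratios free of unit conversions:

* energy in kelvin (the epsilon/k_B convention, i.e. k_B = 1),
* length in nanometers,
* number density in nm^-3,
* pressure in K nm^-3,
* surface tension in K nm^-2.

Conversions to laboratory units (kg/m^3, MPa, mN/m) happen only at the I/O
boundary, using the molar mass of water.
"""

from __future__ import annotations

#: Boltzmann constant, J/K
KB_J = 1.380649e-23

#: Avogadro constant, 1/mol
N_AVOGADRO = 6.02214076e23

#: Molar mass of water, g/mol
WATER_MOLAR_MASS = 18.015

#: 1 K nm^-3 of pressure expressed in MPa
PRESSURE_K_PER_NM3_TO_MPA = KB_J / 1e-27 / 1e6  # = 0.01380649

#: 1 K nm^-2 of surface tension expressed in mN/m
GAMMA_K_PER_NM2_TO_MN_PER_M = KB_J / 1e-18 * 1e3  # = 0.01380649


def number_density_to_kg_m3(rho_nm3: float, molar_mass: float = WATER_MOLAR_MASS) -> float:
    """Convert a number density in nm^-3 to a mass density in kg/m^3."""
    return rho_nm3 * (molar_mass * 1e-3 / N_AVOGADRO) * 1e27


def kg_m3_to_number_density(rho_kg_m3: float, molar_mass: float = WATER_MOLAR_MASS) -> float:
    """Convert a mass density in kg/m^3 to a number density in nm^-3."""
    return rho_kg_m3 / ((molar_mass * 1e-3 / N_AVOGADRO) * 1e27)


def pressure_to_mpa(p_k_nm3: float) -> float:
    """Convert a pressure in K nm^-3 (k_B = 1) to MPa."""
    return p_k_nm3 * PRESSURE_K_PER_NM3_TO_MPA


def mpa_to_pressure(p_mpa: float) -> float:
    """Convert a pressure in MPa to K nm^-3 (k_B = 1)."""
    return p_mpa / PRESSURE_K_PER_NM3_TO_MPA


def gamma_to_mn_per_m(gamma_k_nm2: float) -> float:
    """Convert a surface tension in K nm^-2 (k_B = 1) to mN/m."""
    return gamma_k_nm2 * GAMMA_K_PER_NM2_TO_MN_PER_M
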