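"""Vapor-liquid equilibrium solver for any registered equation of state.

Coexistence at temperature T requires equal pressure and equal chemical
potential in the two phases.  The solver proceeds in two stages:

1. a spinodal scan on a dense density grid locates the mechanically
   unstable window (dp/drho < 0) that separates the vapor and liquid
   branches;
2. an outer Brent iteration on the pressure drives the chemical-potential
   difference mu_l(p) - mu_v(p) to zero, with the phase densities at each
   trial pressure obtained by Brent root-finding of p(rho) = p on the two
   stable branches.

If the isotherm is monotone (no spinodal window) the state is supercritical
and ``SupercriticalError`` is raised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .models import EoSModel, chemical_potential, pressure_from_eos

__all__ = ["VLEResult", "SupercriticalError", "solve_vle"]


class SupercriticalError(RuntimeError):
    """No two-phase solution exists at the requested temperature."""


@dataclass(frozen=True)
class VLEResult:
    """Coexistence densities (nm^-3) and vapor pressure (K nm^-3)."""

    T: float
    rho_l: float
    rho_v: float
    p_v: float


def _spinodal_window(T: float, model: EoSModel, rho_hi: float, n_scan: int):
    """Return (rho at the vapor-side pressure maximum, liquid-side minimum)."""
    rho = np.geomspace(rho_hi * 1e-9, rho_hi, n_scan)
    p = np.asarray(pressure_from_eos(rho, T, model))
    dp = np.diff(p)
    falling = dp < 0
    if not falling.any():
        raise SupercriticalError(f"isotherm at T = {T} K is monotone: supercritical")
    i0 = int(np.argmax(falling))                      # first descent
    i1 = i0 + int(np.argmax(~falling[i0:]))           # descent ends
    if i1 == i0:  # descending to the end of the grid: no liquid branch resolved
        raise SupercriticalError(
            f"no stable liquid branch below rho = {rho_hi} nm^-3 at T = {T} K"
        )
    return rho[i0], rho[i1]


def solve_vle(
    T: float,
    model: EoSModel,
    rtol: float = 1e-8,
    n_scan: int = 2000,
) -> VLEResult:
    """Solve vapor-liquid coexistence of ``model`` at temperature ``T``.

    Raises
    ------
    SupercriticalError
        If the isotherm has no van der Waals loop (T at or above the model's
        critical temperature, or the model has no attraction at all).
    """
    model.validate_temperature(T)
    rho_hi = min(model.rho_max(T) * 0.999, 1e6)
    rho_sp_v, rho_sp_l = _spinodal_window(T, model, rho_hi, n_scan)

    p_max = pressure_from_eos(rho_sp_v, T, model)  # local maximum (vapor side)
    p_min = pressure_from_eos(rho_sp_l, T, model)  # local minimum (liquid side)
    p_lo = max(p_min, p_max * 1e-12)
    p_hi = p_max

    def roots_at(p: float) -> tuple[float, float]:
        # on the vapor branch p(rho) <= rho*T (sub-ideal), so p/(10 T) is a
        # guaranteed under-bracket; expand further down if needed
        r_lo = min(p / (10.0 * T), rho_sp_v * 0.1)
        while pressure_from_eos(r_lo, T, model) >= p:
            r_lo *= 0.1
            if r_lo < 1e-300:
                raise SupercriticalError(f"no vapor root at p = {p}, T = {T} K")
        rv = brentq(
            lambda r: pressure_from_eos(r, T, model) - p,
            r_lo,
            rho_sp_v,
            xtol=1e-300,
            rtol=1e-14,
        )
        rl = brentq(
            lambda r: pressure_from_eos(r, T, model) - p,
            rho_sp_l,
            rho_hi,
            xtol=1e-300,
            rtol=1e-14,
        )
        return rv, rl

    def mu_gap(p: float) -> float:
        rv, rl = roots_at(p)
        return chemical_potential(rl, T, model) - chemical_potential(rv, T, model)

    # shrink the bracket until the chemical-potential gap changes sign
    g_lo, g_hi = mu_gap(p_lo * (1 + 1e-12)), mu_gap(p_hi * (1 - 1e-12))
    if g_lo * g_hi > 0:
        raise SupercriticalError(
            f"no coexistence pressure bracketed at T = {T} K (near-critical state)"
        )
    p_v = brentq(mu_gap, p_lo * (1 + 1e-12), p_hi * (1 - 1e-12), rtol=rtol * 1e-2)
    rho_v, rho_l = roots_at(p_v)
    return VLEResult(T=T, rho_l=rho_l, rho_v=rho_v, p_v=p_v)
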