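"""Measurement suite: profiles, coexistence densities, ghost-perturbation
estimators for surface tension and pressure, fluctuation compressibility,
and %AAD scoring.

The test-area and test-volume estimators evaluate the energy of *ghost*
deformations of sampled frames (never accepted into the trajectory): a
free-energy difference follows from the exponential average of the energy
change, and a central difference of the + and - deformations gives the
surface tension or pressure.  Uncertainties come from block averaging
(20 blocks by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from . import _kernels
from .ldp_core import Configuration, PotentialSpec

__all__ = [
    "DensityProfile",
    "CoexistenceResult",
    "TestAreaSettings",
    "TestVolumeSettings",
    "Estimate",
    "block_average",
    "density_profile",
    "coexistence_densities",
    "test_area_gamma",
    "test_volume_pressure",
    "isothermal_compressibility",
    "percent_aad",
]

N_BLOCKS = 20


@dataclass(frozen=True)
class Estimate:
    """A scalar estimate with a block-averaged standard error."""

    value: float
    error: float


def block_average(series: np.ndarray, n_blocks: int = N_BLOCKS) -> Estimate:
    """Mean and standard error of the mean from block averaging."""
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("need at least two samples")
    n_blocks = min(n_blocks, series.size)
    blocks = np.array_split(series, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return Estimate(float(series.mean()), float(means.std(ddof=1) / np.sqrt(n_blocks)))


@dataclass
class DensityProfile:
    """Frame-averaged number-density histogram along z."""

    z_centers: np.ndarray  # nm
    density: np.ndarray  # nm^-3
    n_bins: int
    lz: float
    area: float  # Lx * Ly, nm^2


@dataclass
class CoexistenceResult:
    """Liquid/vapor densities read off a two-plateau density profile."""

    rho_l: float
    rho_v: float
    interface_width: float
    has_coexistence: bool
    fit_residual: float = np.nan


@dataclass(frozen=True)
class TestAreaSettings:
    """Fractional area perturbation for the test-area estimator.

    xi must be small enough for the linear-response regime; results should
    be insensitive to halving xi (checked in the test suite).
    """

    xi: float = 5e-4

    def __post_init__(self) -> None:
        if not (0 < self.xi < 0.1):
            raise ValueError("xi must lie in (0, 0.1)")


@dataclass(frozen=True)
class TestVolumeSettings:
    """Relative ghost volume perturbation zeta = dV/V along direction alpha."""

    zeta: float = 1e-4
    alpha: int = 0  # 0 = x, 1 = y, 2 = z

    def __post_init__(self) -> None:
        if self.zeta <= 0:
            raise ValueError("zeta must be positive")
        if self.alpha not in (0, 1, 2):
            raise ValueError("alpha must be one of 0, 1, 2")


def density_profile(frames: list[Configuration], n_bins: int) -> DensityProfile:
    """Histogram of particle z coordinates, averaged over frames.

    The sum of bin density times bin volume recovers N for every frame.
    """
    if not frames:
        raise ValueError("at least one frame is required")
    if n_bins < 10:
        raise ValueError("need at least 10 bins")
    lz = float(frames[0].box[2])
    area = float(frames[0].box[0] * frames[0].box[1])
    edges = np.linspace(0.0, lz, n_bins + 1)
    counts = np.zeros(n_bins)
    for fr in frames:
        if abs(fr.box[2] - lz) > 1e-9:
            raise ValueError("frames must share the same box for a profile")
        h, _ = np.histogram(fr.positions[:, 2], bins=edges)
        counts += h
    bin_vol = area * lz / n_bins
    density = counts / (len(frames) * bin_vol)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(z_centers=centers, density=density, n_bins=n_bins, lz=lz, area=area)


def _slab_model(z, rho_v, rho_l, z1, z2, d):
    return rho_v + 0.5 * (rho_l - rho_v) * (
        np.tanh((z - z1) / d) - np.tanh((z - z2) / d)
    )


def coexistence_densities(profile: DensityProfile) -> CoexistenceResult:
    """Fit a hyperbolic-tangent slab and average the plateau bins.

    Bins deeper than the 10-90 interface bounds of the fit contribute to
    the liquid and vapor plateau averages.  Returns a "no coexistence"
    result if the profile has no two-plateau structure.
    """
    z = profile.z_centers
    rho = profile.density
    lz = profile.lz
    rho_min, rho_max = float(rho.min()), float(rho.max())
    if rho_max - rho_min < 0.05 * max(rho_max, 1e-300):
        return CoexistenceResult(np.nan, np.nan, np.nan, has_coexistence=False)

    # center the liquid slab at lz/2 so the two interfaces sit inside the box
    shift_bins = int(np.argmax(rho)) - profile.n_bins // 2
    rho_c = np.roll(rho, -shift_bins)
    p0 = (rho_min, rho_max, lz * 0.3, lz * 0.7, lz * 0.03)
    try:
        popt, _ = curve_fit(_slab_model, z, rho_c, p0=p0, maxfev=20000)
    except RuntimeError:
        return CoexistenceResult(np.nan, np.nan, np.nan, has_coexistence=False)
    rho_v, rho_l, z1, z2, d = popt
    if not (z2 > z1 and rho_l > rho_v >= -1e-12 and 0 < z1 < lz and 0 < z2 < lz):
        return CoexistenceResult(np.nan, np.nan, np.nan, has_coexistence=False)
    resid = float(np.sqrt(np.mean((_slab_model(z, *popt) - rho_c) ** 2)))

    # 10-90 width of a tanh is 2 * atanh(0.8) * d; plateau averages use the
    # wider 1-99 cut, because bins at the 10% level still carry interface
    # density and bias the plateau mean by ~1%
    half_width = np.arctanh(0.8) * abs(d)
    plateau_cut = np.arctanh(0.98) * abs(d)
    liq = (z > z1 + plateau_cut) & (z < z2 - plateau_cut)
    vap = (z < z1 - plateau_cut) | (z > z2 + plateau_cut)
    if liq.sum() < 1 or vap.sum() < 1:
        return CoexistenceResult(np.nan, np.nan, np.nan, has_coexistence=False)
    return CoexistenceResult(
        rho_l=float(rho_c[liq].mean()),
        rho_v=float(rho_c[vap].mean()),
        interface_width=float(2 * half_width),
        has_coexistence=True,
        fit_residual=resid,
    )


def _frame_energy(positions, box, spec: PotentialSpec) -> float:
    rho, grad = _kernels.field_kernel(positions, box, spec.r_c)
    u, _ = _kernels.spline_energy(
        rho, grad, spec.lookup.coeffs, spec.lookup.dx, spec.kappa, spec.lookup.rho_max
    )
    return u


def _ghost_du(frame: Configuration, spec: PotentialSpec, scale: np.ndarray) -> float:
    """Energy change for a ghost affine deformation of a frame."""
    u0 = _frame_energy(frame.positions, frame.box, spec)
    u1 = _frame_energy(frame.positions * scale, frame.box * scale, spec)
    return u1 - u0


def test_area_gamma(
    frames: list[Configuration],
    spec: PotentialSpec,
    settings: TestAreaSettings,
    T: float,
) -> Estimate:
    """Surface tension (K nm^-2) from ghost area perturbations.

    The interface normal must lie along z.  Each frame is deformed by
    scaling (Lx, Ly) with sqrt(1 +/- xi) and Lz with 1/(1 +/- xi) (volume
    preserved, box-relative positions unchanged); the free-energy changes
    dA± = -T ln<exp(-dU±/T)> combine into the central difference

        gamma = (dA+ - dA-) / (2 xi A_total),  A_total = 2 Lx Ly

    (two interfaces in a periodic slab).  Perturbations are never accepted.
    """
    if not frames:
        raise ValueError("at least one frame is required")
    spec.ensure_lookup()
    xi = settings.xi
    box = frames[0].box
    if not (box[2] >= box[0] and box[2] >= box[1]):
        raise ValueError("slab geometry required: Lz must be the long axis")
    s_plus = np.array([np.sqrt(1 + xi), np.sqrt(1 + xi), 1.0 / (1 + xi)])
    s_minus = np.array([np.sqrt(1 - xi), np.sqrt(1 - xi), 1.0 / (1 - xi)])
    du_p = np.array([_ghost_du(fr, spec, s_plus) for fr in frames])
    du_m = np.array([_ghost_du(fr, spec, s_minus) for fr in frames])

    def gamma_of(du_p_blk, du_m_blk, a0_total):
        da_p = -T * np.log(np.mean(np.exp(-du_p_blk / T)))
        da_m = -T * np.log(np.mean(np.exp(-du_m_blk / T)))
        return (da_p - da_m) / (2.0 * xi * a0_total)

    a0_total = 2.0 * box[0] * box[1]
    value = gamma_of(du_p, du_m, a0_total)
    n_blocks = min(N_BLOCKS, len(frames))
    if n_blocks >= 2:
        idx = np.array_split(np.arange(len(frames)), n_blocks)
        g_blocks = np.array([gamma_of(du_p[k], du_m[k], a0_total) for k in idx])
        err = float(g_blocks.std(ddof=1) / np.sqrt(n_blocks))
    else:
        err = np.nan
    return Estimate(float(value), err)


def test_volume_pressure(
    frames: list[Configuration],
    spec: PotentialSpec,
    settings: TestVolumeSettings,
    T: float,
) -> Estimate:
    """Pressure component p_aa (K nm^-3) from ghost volume perturbations.

    Positions and box are rescaled by (1 +/- zeta) along direction alpha
    only; for each sign

        p± = (T / ±dV) [ N ln(V1/V0) + ln<exp(-dU±/T)> ],

    and the reported value is the average of the + and - estimates.  For an
    ideal gas (dU = 0) this reduces to rho T exactly as zeta -> 0.
    """
    if not frames:
        raise ValueError("at least one frame is required")
    spec.ensure_lookup()
    zeta = settings.zeta
    n = frames[0].n_particles
    if n == 0:
        return Estimate(0.0, 0.0)
    scale_p = np.ones(3)
    scale_p[settings.alpha] = 1.0 + zeta
    scale_m = np.ones(3)
    scale_m[settings.alpha] = 1.0 - zeta
    du_p = np.array([_ghost_du(fr, spec, scale_p) for fr in frames])
    du_m = np.array([_ghost_du(fr, spec, scale_m) for fr in frames])
    v0 = frames[0].volume

    def p_of(du_p_blk, du_m_blk):
        pp = (T / (zeta * v0)) * (n * np.log(1 + zeta) + np.log(np.mean(np.exp(-du_p_blk / T))))
        pm = (T / (-zeta * v0)) * (n * np.log(1 - zeta) + np.log(np.mean(np.exp(-du_m_blk / T))))
        return 0.5 * (pp + pm)

    value = p_of(du_p, du_m)
    n_blocks = min(N_BLOCKS, len(frames))
    if n_blocks >= 2:
        idx = np.array_split(np.arange(len(frames)), n_blocks)
        p_blocks = np.array([p_of(du_p[k], du_m[k]) for k in idx])
        err = float(p_blocks.std(ddof=1) / np.sqrt(n_blocks))
    else:
        err = np.nan
    return Estimate(float(value), err)


def isothermal_compressibility(v_series: np.ndarray, T: float) -> Estimate:
    """beta_T = (<V^2> - <V>^2) / (T <V>) from an NpT volume series (nm^3/K).

    Uncertainty from block averaging of per-block fluctuation estimates.
    """
    v = np.asarray(v_series, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two volume samples")
    var = float(np.var(v))
    value = var / (T * float(v.mean()))
    n_blocks = min(N_BLOCKS, v.size // 5)
    if n_blocks >= 2:
        blocks = np.array_split(v, n_blocks)
        vals = np.array([np.var(b) / (T * b.mean()) for b in blocks])
        err = float(vals.std(ddof=1) / np.sqrt(n_blocks))
    else:
        err = np.nan
    return Estimate(value, err)


def percent_aad(sim_values, ref_values) -> float:
    """Percent absolute average deviation, (100/n) sum |(sim - ref)/ref|."""
    sim = np.asarray(sim_values, dtype=float)
    ref = np.asarray(ref_values, dtype=float)
    if sim.shape != ref.shape or sim.size == 0:
        raise ValueError("inputs must be equal-length, non-empty")
    if np.any(ref == 0):
        raise ValueError("reference values must be nonzero")
    return float(100.0 * np.mean(np.abs((sim - ref) / ref)))
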