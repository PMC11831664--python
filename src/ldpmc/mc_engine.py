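"""Metropolis Monte Carlo in the NVT and NpT ensembles.

Single-particle displacement moves update the local-density field
incrementally (see :mod:`ldpmc._kernels`); NpT volume moves are sampled in
ln V with isotropic rescaling and a full field recomputation.  Step sizes
adapt toward a target acceptance only during equilibration and are frozen
for production, so the sampled distribution is unbiased.  Identical
protocol + seed gives a bit-identical trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Literal, NamedTuple

import numpy as np

from . import _kernels
from .ldp_core import Configuration, LocalDensityField, PotentialSpec, _check_box

__all__ = [
    "SimulationProtocol",
    "ObservableRecord",
    "EnergyBookkeepingError",
    "metropolis_accept",
    "run_nvt",
    "run_npt",
]

logger = logging.getLogger(__name__)

#: displacement acceptance targeted during equilibration
TARGET_ACCEPTANCE = 0.35


class EnergyBookkeepingError(RuntimeError):
    """Cached energy diverged from a from-scratch recomputation."""


@dataclass
class SimulationProtocol:
    """Ensemble, state point and move settings of one MC run.

    A cycle is N attempted single-particle displacements; in NpT,
    ``volume_moves_per_cycle`` ln-V moves are attempted after each cycle.
    ``max_displacement`` (nm) and ``max_lnv_step`` are initial step sizes;
    both adapt toward 35% acceptance during equilibration only.
    """

    T: float
    ensemble: Literal["nvt", "npt"] = "nvt"
    p: float | None = None  # K nm^-3, required for NpT
    n_equil_cycles: int = 1000
    n_prod_cycles: int = 2000
    max_displacement: float = 0.3
    max_lnv_step: float = 0.02
    volume_moves_per_cycle: int = 1
    seed: int = 0
    sampling_stride: int = 10
    adapt_interval: int = 100
    energy_refresh_interval: int = 200

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.ensemble not in ("nvt", "npt"):
            raise ValueError(f"unknown ensemble {self.ensemble!r}")
        if self.ensemble == "npt":
            if self.p is None or self.p <= 0:
                raise ValueError("NpT runs require a positive pressure")
        if self.n_equil_cycles < 0 or self.n_prod_cycles < 0:
            raise ValueError("cycle counts must be non-negative")


@dataclass
class ObservableRecord:
    """Time series and summary statistics collected during production."""

    u_series: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    v_series: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    rho_series: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    acceptance_displacement: float = np.nan
    acceptance_volume: float = np.nan
    final_max_displacement: float = np.nan
    final_max_lnv_step: float = np.nan
    energy_drift: float = np.nan
    n_lookup_overflows: int = 0
    n_rejected_small_box: int = 0


class RunResult(NamedTuple):
    config: Configuration
    record: ObservableRecord
    frames: list[Configuration]


def metropolis_accept(delta_u: float, T: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(-delta_u / T)); k_B = 1."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if delta_u <= 0.0:
        return True
    if np.isinf(delta_u):
        return False
    return rng.random() < np.exp(-delta_u / T)


def _prepare(config: Configuration, spec: PotentialSpec, protocol: SimulationProtocol):
    if abs(spec.T - protocol.T) > 1e-12:
        raise ValueError(
            f"potential specified at T = {spec.T} K but protocol at T = {protocol.T} K"
        )
    _check_box(config, spec.r_c)
    spec.ensure_lookup()
    rho, grad = _kernels.field_kernel(config.positions, config.box, spec.r_c)
    u, n_out = _kernels.spline_energy(
        rho, grad, spec.lookup.coeffs, spec.lookup.dx, spec.kappa, spec.lookup.rho_max
    )
    return rho, grad, u, n_out


def _recompute(config: Configuration, spec: PotentialSpec):
    rho, grad = _kernels.field_kernel(config.positions, config.box, spec.r_c)
    u, n_out = _kernels.spline_energy(
        rho, grad, spec.lookup.coeffs, spec.lookup.dx, spec.kappa, spec.lookup.rho_max
    )
    return rho, grad, u, n_out


def _adapt(step: float, accepted: int, attempted: int, lo: float, hi: float) -> float:
    if attempted == 0:
        return step
    ratio = accepted / attempted
    step *= 1.1 if ratio > TARGET_ACCEPTANCE else 0.9
    return float(np.clip(step, lo, hi))


def run_nvt(
    config: Configuration, spec: PotentialSpec, protocol: SimulationProtocol
) -> RunResult:
    """Canonical-ensemble run; returns final config, record, sampled frames.

    Energy bookkeeping is verified against a from-scratch recomputation at
    the end of the run (<= 1e-6 relative, else ``EnergyBookkeepingError``).
    """
    if protocol.ensemble != "nvt":
        raise ValueError("protocol.ensemble must be 'nvt'")
    return _run(config, spec, protocol, do_volume_moves=False)


def run_npt(
    config: Configuration, spec: PotentialSpec, protocol: SimulationProtocol
) -> RunResult:
    """Isobaric-isothermal run: displacement sweeps plus ln-V volume moves.

    The volume series (one entry per production cycle) feeds the
    fluctuation estimator of the isothermal compressibility.
    """
    if protocol.ensemble != "npt":
        raise ValueError("protocol.ensemble must be 'npt'")
    return _run(config, spec, protocol, do_volume_moves=True)


def _run(
    config: Configuration,
    spec: PotentialSpec,
    protocol: SimulationProtocol,
    do_volume_moves: bool,
) -> RunResult:
    config = config.copy()
    rho, grad, u_cache, n_out_total = _prepare(config, spec, protocol)
    rng = np.random.default_rng(protocol.seed)
    n = config.n_particles
    beta = 1.0 / protocol.T
    max_disp = protocol.max_displacement
    max_lnv = protocol.max_lnv_step
    record = ObservableRecord()
    frames: list[Configuration] = []
    u_list: list[float] = []
    v_list: list[float] = []
    rho_list: list[float] = []

    lookup = spec.lookup
    assert lookup is not None

    def sweep_chunk(n_cycles: int, disp: float):
        nonlocal u_cache, n_out_total
        du, acc, att, n_out = _kernels.sweep_kernel(
            config.positions,
            config.box,
            rho,
            grad,
            lookup.coeffs,
            lookup.dx,
            lookup.rho_max,
            spec.r_c,
            spec.kappa,
            beta,
            disp,
            n_cycles,
            rng,
        )
        u_cache += du
        n_out_total += n_out
        return acc, att

    def volume_move() -> bool:
        nonlocal u_cache, rho, grad, n_out_total
        v0 = config.volume
        lnv1 = np.log(v0) + (2.0 * rng.random() - 1.0) * max_lnv
        v1 = np.exp(lnv1)
        s = (v1 / v0) ** (1.0 / 3.0)
        new_box = config.box * s
        if np.min(new_box) < 2.0 * spec.r_c:
            record.n_rejected_small_box += 1
            return False
        new_pos = config.positions * s
        rho1, grad1 = _kernels.field_kernel(new_pos, new_box, spec.r_c)
        u1, n_out = _kernels.spline_energy(
            rho1, grad1, lookup.coeffs, lookup.dx, spec.kappa, lookup.rho_max
        )
        n_out_total += n_out
        dh = (u1 - u_cache) + protocol.p * (v1 - v0) - (n + 1) * protocol.T * np.log(v1 / v0)
        if metropolis_accept(dh, protocol.T, rng):
            config.positions[:] = new_pos
            config.box[:] = new_box
            rho[:] = rho1
            grad[:] = grad1
            u_cache = u1
            return True
        return False

    # ---- equilibration with step adaptation
    cycles_left = protocol.n_equil_cycles
    while cycles_left > 0:
        chunk = min(protocol.adapt_interval, cycles_left)
        if do_volume_moves:
            acc = att = 0
            v_acc = v_att = 0
            for _ in range(chunk):
                a, t = sweep_chunk(1, max_disp)
                acc += a
                att += t
                for _ in range(protocol.volume_moves_per_cycle):
                    v_att += 1
                    v_acc += volume_move()
            max_lnv = _adapt(max_lnv, v_acc, v_att, 1e-6, 0.5)
        else:
            acc, att = sweep_chunk(chunk, max_disp)
        max_disp = _adapt(max_disp, acc, att, 1e-5, float(np.min(config.box)) / 2.0)
        cycles_left -= chunk
        rho, grad, u_cache, _ = _refresh(config, spec, rho, grad, u_cache)

    # ---- production: step sizes frozen
    acc_tot = att_tot = 0
    v_acc_tot = v_att_tot = 0
    cycles_done = 0
    while cycles_done < protocol.n_prod_cycles:
        chunk = min(protocol.sampling_stride, protocol.n_prod_cycles - cycles_done)
        if do_volume_moves:
            for _ in range(chunk):
                a, t = sweep_chunk(1, max_disp)
                acc_tot += a
                att_tot += t
                for _ in range(protocol.volume_moves_per_cycle):
                    v_att_tot += 1
                    v_acc_tot += volume_move()
                v_list.append(config.volume)
                rho_list.append(n / config.volume)
        else:
            a, t = sweep_chunk(chunk, max_disp)
            acc_tot += a
            att_tot += t
        cycles_done += chunk
        u_list.append(u_cache)
        frames.append(config.copy())
        if cycles_done % protocol.energy_refresh_interval < protocol.sampling_stride:
            rho, grad, u_cache, _ = _refresh(config, spec, rho, grad, u_cache)
        if cycles_done % 1000 < protocol.sampling_stride:
            logger.info(
                "cycle %d: U/N = %.4f K, V = %.3f nm^3, acc = %.3f",
                cycles_done,
                u_cache / n,
                config.volume,
                acc_tot / max(att_tot, 1),
            )

    # ---- final exact bookkeeping check
    rho2, grad2, u2, _ = _recompute(config, spec)
    drift = abs(u_cache - u2) / max(1.0, abs(u2))
    if drift > 1e-6:
        raise EnergyBookkeepingError(
            f"cached energy {u_cache} vs recomputed {u2} (relative drift {drift:.2e})"
        )
    record.energy_drift = drift
    record.u_series = np.asarray(u_list)
    record.v_series = np.asarray(v_list)
    record.rho_series = np.asarray(rho_list)
    record.acceptance_displacement = acc_tot / max(att_tot, 1)
    record.acceptance_volume = v_acc_tot / max(v_att_tot, 1) if v_att_tot else np.nan
    record.final_max_displacement = max_disp
    record.final_max_lnv_step = max_lnv
    record.n_lookup_overflows = n_out_total
    if n_out_total:
        logger.warning(
            "%d local-density evaluations beyond the lookup range "
            "(continued linearly with the end slope)",
            n_out_total,
        )
    return RunResult(config=config, record=record, frames=frames)


def _refresh(config, spec, rho, grad, u_cache):
    """Replace cached field/energy by a from-scratch recomputation."""
    rho2, grad2, u2, n_out = _recompute(config, spec)
    rho[:] = rho2
    grad[:] = grad2
    return rho, grad, u2, n_out
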