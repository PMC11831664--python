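"""Calibration of the square-gradient coefficient against surface tension.

The interfacial energy of the model has two parts: the contribution the
local-density functional produces on its own, and the square-gradient term
whose prefactor kappa is a free parameter.  Because the square-gradient
energy is linear in kappa, the measured surface tension of a slab is, to a
good approximation, linear in kappa as well: gamma(kappa) = a + b*kappa.
Calibration therefore runs a small sweep of slab simulations over a kappa
grid, fits that line by weighted least squares, and solves for the kappa
that reproduces a target surface tension.  A state-dependent kappa(T) is
then represented as a low-order polynomial fitted through per-temperature
calibrations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KappaCalibration",
    "calibrate_kappa",
    "fit_kappa_polynomial",
    "KappaPolynomial",
]

logger = logging.getLogger(__name__)

#: below this R^2 the gamma(kappa) response is flagged as non-linear
R2_LINEARITY_THRESHOLD = 0.98


@dataclass(frozen=True)
class KappaCalibration:
    """Result of a single-temperature kappa calibration.

    ``kappa_star`` solves a + b*kappa = gamma_target on the fitted line;
    units: kappa in K nm^8, gamma in K nm^-2.
    """

    T: float
    gamma_target: float
    kappa_grid: np.ndarray
    gamma_values: np.ndarray
    gamma_errors: np.ndarray
    intercept: float
    slope: float
    r_squared: float
    kappa_star: float
    kappa_star_error: float
    linear: bool

    def to_dict(self) -> dict:
        return {
            "T_K": self.T,
            "gamma_target_K_per_nm2": self.gamma_target,
            "kappa_grid_K_nm8": list(map(float, self.kappa_grid)),
            "gamma_values_K_per_nm2": list(map(float, self.gamma_values)),
            "gamma_errors_K_per_nm2": list(map(float, self.gamma_errors)),
            "intercept_K_per_nm2": self.intercept,
            "slope_per_nm10": self.slope,
            "r_squared": self.r_squared,
            "kappa_star_K_nm8": self.kappa_star,
            "kappa_star_error_K_nm8": self.kappa_star_error,
            "linear_response": self.linear,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kappa_K_nm8": self.kappa_grid,
                "gamma_K_per_nm2": self.gamma_values,
                "gamma_err_K_per_nm2": self.gamma_errors,
            }
        )


def calibrate_kappa(
    kappa_grid,
    gamma_values,
    gamma_errors,
    gamma_target: float,
    T: float,
) -> KappaCalibration:
    """Fit gamma = a + b*kappa by weighted least squares and invert for kappa.

    ``gamma_errors`` are one-sigma uncertainties used as weights (zero or
    missing errors fall back to equal weights).  Raises if the slope is not
    positive: the square-gradient term must stiffen the interface, so a
    non-positive slope means the sweep data cannot be calibrated.
    """
    kappa = np.asarray(kappa_grid, dtype=float)
    gamma = np.asarray(gamma_values, dtype=float)
    err = np.asarray(gamma_errors, dtype=float)
    if kappa.ndim != 1 or kappa.shape != gamma.shape or kappa.shape != err.shape:
        raise ValueError("kappa grid, gamma values and errors must be 1-D, same length")
    if kappa.size < 3:
        raise ValueError("need at least 3 kappa points to assess linearity")
    if np.unique(kappa).size != kappa.size:
        raise ValueError("kappa grid values must be distinct")

    if np.any(err <= 0) or not np.all(np.isfinite(err)):
        w = np.ones_like(gamma)
    else:
        w = 1.0 / err**2

    # weighted least squares for [a, b]
    x = np.column_stack([np.ones_like(kappa), kappa])
    wx = x * w[:, None]
    cov = np.linalg.inv(x.T @ wx)
    beta = cov @ (wx.T @ gamma)
    a, b = float(beta[0]), float(beta[1])

    fit = a + b * kappa
    ss_res = float(np.sum(w * (gamma - fit) ** 2))
    gbar = float(np.sum(w * gamma) / np.sum(w))
    ss_tot = float(np.sum(w * (gamma - gbar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    if b <= 0:
        raise ValueError(
            f"gamma(kappa) slope is non-positive (b = {b:.4g}); the sweep does not "
            "show the expected stiffening with kappa and cannot be inverted"
        )
    linear = r2 >= R2_LINEARITY_THRESHOLD
    if not linear:
        logger.warning(
            "gamma(kappa) response deviates from linearity (R^2 = %.4f < %.2f); "
            "kappa_star is still reported but should be re-checked with a finer grid",
            r2,
            R2_LINEARITY_THRESHOLD,
        )

    kappa_star = (gamma_target - a) / b
    # first-order error propagation through kappa* = (g - a)/b
    var_a, var_b = cov[0, 0], cov[1, 1]
    cov_ab = cov[0, 1]
    # scale parameter covariance by reduced chi^2 when errors were fallback weights
    dof = max(kappa.size - 2, 1)
    scale = ss_res / dof if np.all(w == 1.0) else 1.0
    da = -1.0 / b
    db = -(gamma_target - a) / b**2
    kappa_star_err = float(
        np.sqrt(scale * (da * da * var_a + db * db * var_b + 2 * da * db * cov_ab))
    )

    return KappaCalibration(
        T=T,
        gamma_target=gamma_target,
        kappa_grid=kappa,
        gamma_values=gamma,
        gamma_errors=err,
        intercept=a,
        slope=b,
        r_squared=r2,
        kappa_star=float(kappa_star),
        kappa_star_error=kappa_star_err,
        linear=linear,
    )


@dataclass(frozen=True)
class KappaPolynomial:
    """kappa(T) polynomial in ascending coefficient order with validity range."""

    coefficients: np.ndarray
    t_range: tuple[float, float]

    def __call__(self, T: float) -> float:
        lo, hi = self.t_range
        if not (lo <= T <= hi):
            logger.warning(
                "kappa(T) evaluated at T = %.1f K outside the fitted range [%.1f, %.1f] K",
                T,
                lo,
                hi,
            )
        return float(np.polynomial.polynomial.polyval(T, self.coefficients))

    def to_dict(self) -> dict:
        return {
            "coefficients_ascending": list(map(float, self.coefficients)),
            "t_range_K": list(self.t_range),
        }


def fit_kappa_polynomial(temperatures, kappa_values, degree: int = 3) -> KappaPolynomial:
    """Fit kappa(T) through per-temperature calibrations.

    Needs at least degree + 1 points; validity range is the span of the
    input temperatures.
    """
    t = np.asarray(temperatures, dtype=float)
    k = np.asarray(kappa_values, dtype=float)
    if t.ndim != 1 or t.shape != k.shape:
        raise ValueError("temperatures and kappa values must be 1-D, same length")
    if t.size < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} calibration points for a degree-{degree} fit"
        )
    if np.unique(t).size != t.size:
        raise ValueError("calibration temperatures must be distinct")
    coeffs = np.polynomial.polynomial.polyfit(t, k, degree)
    return KappaPolynomial(coefficients=coeffs, t_range=(float(t.min()), float(t.max())))
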