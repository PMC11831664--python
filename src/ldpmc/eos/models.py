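"""Equation-of-state models and bulk-property solvers.

Every model exposes the excess Helmholtz free energy per particle
a_ex(rho, T) (kelvin, k_B = 1, rho in nm^-3) with a_ex(0, T) = 0.  Bulk
properties follow from thermodynamic identities:

    p(rho, T)      = rho T + rho^2 da_ex/drho
    mu(rho, T)     = T ln(rho) + a_ex + rho da_ex/drho   (thermal part dropped)
    beta_T(rho, T) = 1 / (rho dp/drho)

Registered named models are read from TOML files shipped with the package
(``ldpmc/data/models``).
"""

from __future__ import annotations

import importlib.resources as resources
import tomllib
from dataclasses import dataclass
from typing import Union

import numpy as np

from .association import AssociationParameters, a_assoc
from .mie import MieParameters, TemperatureDependentMie
from .monomer import ETA_MAX, a_mono, bh_diameter

__all__ = [
    "EoSModel",
    "IdealEoS",
    "VdwEoS",
    "SaftVRMieEoS",
    "vdw_a_excess",
    "a_excess",
    "pressure_from_eos",
    "compressibility_from_eos",
    "chemical_potential",
    "load_model",
    "list_models",
]


class EoSModel:
    """Base class: a named excess free energy a_ex(rho, T) per particle."""

    name: str = "base"
    has_association: bool = False

    def a_excess(self, rho, T: float):
        raise NotImplementedError

    def da_drho(self, rho, T: float):
        """d a_ex / d rho.  Default: Richardson-extrapolated central difference."""
        rho = np.asarray(rho, dtype=float)
        h = np.maximum(rho, 1e-3) * 1e-5
        h = np.where(rho > 0, np.minimum(h, 0.45 * rho), h)  # keep rho-2h >= 0
        # 5-point stencil keeps the truncation error ~h^4
        f = self.a_excess
        out = (
            f(rho - 2 * h, T) - 8.0 * f(rho - h, T) + 8.0 * f(rho + h, T) - f(rho + 2 * h, T)
        ) / (12.0 * h)
        return out if np.ndim(out) else float(out)

    def rho_max(self, T: float) -> float:
        """Upper end of the supported density interval at temperature T."""
        return np.inf

    def validate_temperature(self, T: float) -> None:
        if T <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class IdealEoS(EoSModel):
    """Ideal gas: zero excess free energy."""

    name: str = "ideal"
    has_association: bool = False

    def a_excess(self, rho, T: float):
        rho = np.asarray(rho, dtype=float)
        out = np.zeros_like(rho)
        return out if out.ndim else 0.0

    def da_drho(self, rho, T: float):
        rho = np.asarray(rho, dtype=float)
        out = np.zeros_like(rho)
        return out if out.ndim else 0.0


@dataclass(frozen=True)
class VdwEoS(EoSModel):
    """van der Waals fluid, a_ex = -T ln(1 - b rho) - a rho.

    Serves as the closed-form oracle backend in tests: every bulk property
    has an analytic expression.  ``a`` in K nm^3, ``b`` in nm^3.
    """

    a: float = 67.63
    b: float = 0.03097
    name: str = "vdw"
    has_association: bool = False

    def a_excess(self, rho, T: float):
        return vdw_a_excess(rho, T, self.a, self.b)

    def da_drho(self, rho, T: float):
        rho = np.asarray(rho, dtype=float)
        out = T * self.b / (1.0 - self.b * rho) - self.a
        return out if out.ndim else float(out)

    def d2a_drho2(self, rho, T: float):
        rho = np.asarray(rho, dtype=float)
        out = T * self.b**2 / (1.0 - self.b * rho) ** 2
        return out if out.ndim else float(out)

    def rho_max(self, T: float) -> float:
        return 1.0 / self.b

    @property
    def critical_temperature(self) -> float:
        return 8.0 * self.a / (27.0 * self.b)

    @property
    def critical_density(self) -> float:
        return 1.0 / (3.0 * self.b)

    def sigma_equivalent(self) -> float:
        """Effective size from the covolume, b = (2 pi / 3) sigma^3."""
        return (3.0 * self.b / (2.0 * np.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class SaftVRMieEoS(EoSModel):
    """Single-segment SAFT-VR Mie model, optionally with 4-site association.

    The chain term is identically zero (one segment per particle), so
    a_ex = a_mono (+ a_assoc).
    """

    mie: Union[MieParameters, TemperatureDependentMie]
    assoc: AssociationParameters | None = None
    name: str = "saft-vr-mie"

    @property
    def has_association(self) -> bool:  # type: ignore[override]
        return self.assoc is not None

    def mie_at(self, T: float) -> MieParameters:
        if isinstance(self.mie, TemperatureDependentMie):
            return self.mie.at(T)
        return self.mie

    def a_excess(self, rho, T: float):
        p = self.mie_at(T)
        out = a_mono(rho, T, p)
        if self.assoc is not None:
            out = out + a_assoc(rho, T, self.assoc, p)
        return out

    def rho_max(self, T: float) -> float:
        d = bh_diameter(T, self.mie_at(T))
        return 6.0 * ETA_MAX / (np.pi * d**3)


def vdw_a_excess(rho, T: float, a: float, b: float):
    """Closed-form van der Waals excess free energy per particle (kelvin)."""
    rho = np.asarray(rho, dtype=float)
    if np.any(b * rho >= 1.0):
        raise ValueError("density at or above the van der Waals covolume limit (b rho >= 1)")
    out = -T * np.log1p(-b * rho) - a * rho
    return out if out.ndim else float(out)


def a_excess(rho, T: float, model: EoSModel):
    """Excess Helmholtz free energy per particle for any registered model."""
    model.validate_temperature(T)
    return model.a_excess(rho, T)


def pressure_from_eos(rho, T: float, model: EoSModel):
    """Pressure p = rho T + rho^2 da_ex/drho, in K nm^-3."""
    model.validate_temperature(T)
    rho = np.asarray(rho, dtype=float)
    out = rho * T + rho**2 * np.asarray(model.da_drho(rho, T))
    return out if out.ndim else float(out)


def chemical_potential(rho, T: float, model: EoSModel):
    """Chemical potential (kelvin) up to the density-independent thermal part."""
    model.validate_temperature(T)
    rho = np.asarray(rho, dtype=float)
    out = T * np.log(rho) + np.asarray(model.a_excess(rho, T)) + rho * np.asarray(
        model.da_drho(rho, T)
    )
    return out if out.ndim else float(out)


def _dp_drho(rho, T: float, model: EoSModel):
    if isinstance(model, IdealEoS):
        return np.broadcast_to(T, np.shape(rho)).copy() if np.ndim(rho) else T
    if isinstance(model, VdwEoS):
        rho = np.asarray(rho, dtype=float)
        out = T / (1.0 - model.b * rho) ** 2 - 2.0 * model.a * rho
        return out if out.ndim else float(out)
    rho = np.asarray(rho, dtype=float)
    h = np.maximum(rho, 1e-3) * 1e-6
    h = np.where(rho > 0, np.minimum(h, 0.45 * rho), h)
    out = (pressure_from_eos(rho + h, T, model) - pressure_from_eos(rho - h, T, model)) / (2 * h)
    return out if out.ndim else float(out)


def compressibility_from_eos(rho, T: float, model: EoSModel):
    """Isothermal compressibility beta_T = 1/(rho dp/drho), in nm^3/K."""
    model.validate_temperature(T)
    dpdrho = np.asarray(_dp_drho(rho, T, model))
    if np.any(dpdrho <= 0):
        raise ValueError(
            "dp/drho <= 0: state is inside the spinodal (mechanically unstable)"
        )
    rho = np.asarray(rho, dtype=float)
    out = 1.0 / (rho * dpdrho)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------- registry


def _model_from_toml(doc: dict) -> EoSModel:
    kind = doc.get("kind", "saft-vr-mie")
    name = doc["name"]
    if kind == "ideal":
        return IdealEoS(name=name)
    if kind == "vdw":
        return VdwEoS(a=doc["a_K_nm3"], b=doc["b_nm3"], name=name)
    if kind != "saft-vr-mie":
        raise ValueError(f"unknown model kind {kind!r}")
    assoc = None
    if "assoc" in doc:
        assoc = AssociationParameters(
            epsilon_assoc=doc["assoc"]["epsilon_over_kB"],
            bond_volume=doc["assoc"]["bond_volume_nm3"],
        )
    if "epsilon_coeffs" in doc:
        mie: Union[MieParameters, TemperatureDependentMie] = TemperatureDependentMie(
            epsilon_coeffs=tuple(doc["epsilon_coeffs"]),
            sigma_coeffs=tuple(doc["sigma_coeffs"]),
            lambda_r=doc["lambda_r"],
            lambda_a=doc["lambda_a"],
            t_range=tuple(doc["T_range"]),
        )
    else:
        mie = MieParameters(
            epsilon=doc["epsilon_over_kB"],
            sigma=doc["sigma_nm"],
            lambda_r=doc["lambda_r"],
            lambda_a=doc["lambda_a"],
        )
    return SaftVRMieEoS(mie=mie, assoc=assoc, name=name)


def list_models() -> list[str]:
    """Names of the models shipped in the registry."""
    root = resources.files("ldpmc") / "data" / "models"
    return sorted(p.name.removesuffix(".toml") for p in root.iterdir() if p.name.endswith(".toml"))


def load_model(name: str) -> EoSModel:
    """Load a registered model by name, or a TOML file by path."""
    root = resources.files("ldpmc") / "data" / "models"
    candidate = root / f"{name}.toml"
    try:
        text = candidate.read_text()
    except FileNotFoundError:
        try:
            with open(name, "rb") as fh:
                return _model_from_toml(tomllib.load(fh))
        except FileNotFoundError:
            raise ValueError(
                f"unknown model {name!r}; registered models: {', '.join(list_models())}"
            ) from None
    return _model_from_toml(tomllib.loads(text))
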