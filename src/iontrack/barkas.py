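"""Effective-charge (Barkas) scaling of hydrogen interaction data to light ions.

A partially stripped ion of atomic number Z moving with velocity
``beta = v/c`` carries the velocity-dependent effective charge

    Z_eff(Z, beta) = Z * (1 - exp(-125 * beta * Z**(-2/3)))

(the standard Barkas formula).  Electronic interaction cross sections of
an ion at a given velocity are obtained from those of hydrogen at the
same velocity (same energy per nucleon) through the generalized scaling
factor

    F(Z, beta) = Z_eff(Z, beta)**2 / Z_eff(1, beta)**2 ,

where the denominator - the effective charge of hydrogen squared - makes
the scheme self-consistent (hydrogen scales onto itself exactly) and
extends its applicability down to ~10 keV/u.  F approaches Z**(2/3) at
low velocity and Z**2 at high velocity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import AMU_MEV, BARKAS_CONST, BARKAS_EXP
from .baseline import BaselineTable

__all__ = [
    "IonSpec",
    "SUPPORTED_IONS",
    "get_ion",
    "beta_from_energy",
    "effective_charge",
    "scaling_factor",
    "scaled_stopping",
    "scaled_imfp",
    "zeff_over_beta_sq",
]

#: Below this energy per nucleon (MeV/u) the effective-charge scaling is
#: outside its validated domain (nuclear stopping is no longer negligible).
APPLICABILITY_FLOOR_MEV_U = 0.01


@dataclass(frozen=True)
class IonSpec:
    """A supported ion species: atomic number, mass number, label."""

    Z: int
    A: int
    name: str

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise ValueError(f"atomic number must be >= 1, got {self.Z}")
        if self.A < self.Z:
            raise ValueError(f"mass number {self.A} < atomic number {self.Z}")


SUPPORTED_IONS: dict[str, IonSpec] = {
    "H": IonSpec(1, 1, "H"),
    "He": IonSpec(2, 4, "He"),
    "C": IonSpec(6, 12, "C"),
    "N": IonSpec(7, 14, "N"),
    "O": IonSpec(8, 16, "O"),
    "Ne": IonSpec(10, 20, "Ne"),
}


def get_ion(name: str) -> IonSpec:
    """Look up a supported ion by symbol (H, He, C, N, O, Ne)."""
    try:
        return SUPPORTED_IONS[name]
    except KeyError:
        raise KeyError(
            f"unsupported ion {name!r}; supported: {sorted(SUPPORTED_IONS)}"
        ) from None


def beta_from_energy(energy_mev_u):
    """Relativistic beta = v/c from kinetic energy per nucleon (MeV/u).

    Uses the atomic mass unit rest energy (931.494 MeV) per nucleon, so
    that equal energy per nucleon means equal velocity for all species.
    """
    e = np.asarray(energy_mev_u, dtype=float)
    if np.any(e <= 0.0):
        raise ValueError("energy per nucleon must be > 0")
    gamma = 1.0 + e / AMU_MEV
    beta = np.sqrt(1.0 - 1.0 / gamma**2)
    return beta if beta.ndim else float(beta)


def effective_charge(Z: int, beta):
    """Barkas effective charge Z_eff = Z (1 - exp(-125 beta Z^(-2/3))).

    Evaluated with ``expm1`` so the low-velocity limit Z_eff -> 125 beta
    Z^(1/3) is accurate to machine precision.
    """
    if Z < 1:
        raise ValueError("Z must be >= 1")
    b = np.asarray(beta, dtype=float)
    if np.any(b <= 0.0) or np.any(b >= 1.0):
        raise ValueError("beta must lie in (0, 1)")
    zeff = Z * (-np.expm1(-BARKAS_CONST * b * Z**BARKAS_EXP))
    return zeff if zeff.ndim else float(zeff)


def scaling_factor(Z: int, beta):
    """Generalized Barkas scaling factor F = Z_eff(Z)^2 / Z_eff(1)^2.

    F(1, beta) == 1 identically; Z^(2/3) <= F <= Z^2 with the lower
    bound reached as beta -> 0 and the upper as beta -> 1.
    """
    num = np.asarray(effective_charge(Z, beta))
    den = np.asarray(effective_charge(1, beta))
    f = (num / den) ** 2
    return f if f.ndim else float(f)


def _check_floor(energy_mev_u) -> None:
    if np.any(np.asarray(energy_mev_u) < APPLICABILITY_FLOOR_MEV_U):
        warnings.warn(
            "effective-charge scaling requested below 0.01 MeV/u, outside "
            "its validated domain (nuclear stopping not negligible)",
            stacklevel=3,
        )


def scaled_stopping(ion: IonSpec, energy_mev_u, baseline: BaselineTable):
    """Electronic stopping power (keV/um) of `ion` at E (MeV/u).

    The hydrogen baseline value at the same energy per nucleon is
    multiplied by the generalized scaling factor F(Z, beta(E)).
    """
    _check_floor(energy_mev_u)
    s_h = baseline.stopping_at(energy_mev_u)
    if ion.Z == 1:
        return s_h
    return s_h * scaling_factor(ion.Z, beta_from_energy(energy_mev_u))


def scaled_imfp(ion: IonSpec, energy_mev_u, baseline: BaselineTable):
    """Total inverse mean free path (um^-1) of `ion` at E (MeV/u)."""
    _check_floor(energy_mev_u)
    l_h = baseline.imfp_at(energy_mev_u)
    if ion.Z == 1:
        return l_h
    return l_h * scaling_factor(ion.Z, beta_from_energy(energy_mev_u))


def zeff_over_beta_sq(ion: IonSpec, energy_mev_u):
    """Radiation-quality parameter (Z_eff / beta)^2.

    Monotone decreasing in energy; approaches 15,625 * Z^(2/3) as the
    velocity goes to zero and Z^2/beta^2 ~ Z^2 at high energy.
    """
    beta = beta_from_energy(energy_mev_u)
    zeff = np.asarray(effective_charge(ion.Z, beta))
    q = (zeff / np.asarray(beta)) ** 2
    return q if q.ndim else float(q)
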