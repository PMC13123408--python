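"""Solomon–Bloembergen forward model of the paramagnetic relaxation enhancement.

An unpaired electron (here the S = 7/2 of a Gd³⁺ chelate) enhances the
longitudinal and transverse relaxation of a nearby nucleus through the
electron–nucleus dipolar interaction.  The enhancements Γ₁ and Γ₂ fall off
as r⁻⁶ with the electron–nucleus distance and sample the motional spectral
density J(ω) = τc / (1 + ω²τc²) at the nuclear and electron Larmor
frequencies:

    Γ₁ = (2/15) (μ₀/4π)² γ_I² g_e² μ_B² S(S+1) r⁻⁶ [3 J(ω_I) + 7 J(ω_e)]
    Γ₂ = (1/15) (μ₀/4π)² γ_I² g_e² μ_B² S(S+1) r⁻⁶ [4 τc + 3 J(ω_I) + 13 J(ω_e)]

All internal units are SI (distances in metres, rates in s⁻¹); conversion
from Å is left to callers.  Curie-spin and contact contributions are not
modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "ParamagneticSystem",
    "PREPrediction",
    "spectral_density",
    "pre_gamma1",
    "pre_gamma2",
    "nucleus_scaling_ratio",
]

ANGSTROM = 1e-10  # m

_GAMMA_TABLE: Mapping[str, float] = MappingProxyType(
    {
        # gyromagnetic ratios, rad s^-1 T^-1 (CODATA / standard tabulations)
        "1H": 2.6752218744e8,
        "19F": 2.51815e8,
        "13C": 6.728284e7,
    }
)


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA physical constants used throughout the forward model.

    ``gamma`` maps nucleus names to gyromagnetic ratios in rad s⁻¹ T⁻¹.
    """

    mu0: float = 4.0e-7 * math.pi           # vacuum permeability, T m / A
    muB: float = 9.2740100783e-24           # Bohr magneton, J / T
    hbar: float = 1.054571817e-34           # reduced Planck constant, J s
    ge_default: float = 2.00232             # free-electron g value
    gamma: Mapping[str, float] = field(default_factory=lambda: _GAMMA_TABLE)

    def gamma_of(self, nucleus: str) -> float:
        try:
            return self.gamma[nucleus]
        except KeyError:
            raise KeyError(
                f"unknown nucleus {nucleus!r}; known: {sorted(self.gamma)}"
            ) from None


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class ParamagneticSystem:
    """Electron + nucleus + field: everything Γ₁/Γ₂ depend on except r.

    Parameters
    ----------
    S : electron spin quantum number (7/2 for Gd³⁺), half-integer.
    ge : electron g value.
    tau_c : rotational correlation time of the electron–nucleus vector, s.
        The experimental value for a given chelate is rarely known; 100 ps
        is a plausible order of magnitude for a small Gd³⁺ complex, but any
        quantitative prediction should set this explicitly.
    nucleus : name keying the gyromagnetic-ratio table ("1H", "19F", "13C").
    B0 : static magnetic field, T.
    """

    S: float = 3.5
    ge: float = CONSTANTS.ge_default
    tau_c: float = 100e-12
    nucleus: str = "19F"
    B0: float = 14.09
    constants: PhysicalConstants = CONSTANTS

    def __post_init__(self) -> None:
        if self.S < 0.5 or abs(2 * self.S - round(2 * self.S)) > 1e-9:
            raise ValueError(f"S must be a positive half-integer, got {self.S}")
        if self.tau_c <= 0:
            raise ValueError(f"tau_c must be positive, got {self.tau_c}")
        if self.B0 <= 0:
            raise ValueError(f"B0 must be positive, got {self.B0}")
        self.constants.gamma_of(self.nucleus)  # validate nucleus early

    @property
    def gamma_I(self) -> float:
        """Nuclear gyromagnetic ratio, rad s⁻¹ T⁻¹."""
        return self.constants.gamma_of(self.nucleus)

    @property
    def omega_I(self) -> float:
        """Nuclear Larmor angular frequency γ_I·B0, rad/s."""
        return self.gamma_I * self.B0

    @property
    def omega_e(self) -> float:
        """Electron Larmor angular frequency g_e·μ_B·B0/ħ, rad/s."""
        c = self.constants
        return self.ge * c.muB * self.B0 / c.hbar


@dataclass(frozen=True)
class PREPrediction:
    """Predicted PRE rates at one electron–nucleus distance."""

    gamma1: float  # s^-1
    gamma2: float  # s^-1
    r: float       # m


def spectral_density(omega: float, tau_c: float) -> float:
    """Lorentzian spectral density J(ω) = τc / (1 + ω²τc²), in seconds.

    Monotonically decreasing in ω, bounded above by τc (the ω = 0 limit),
    half-maximum at ωτc = 1.
    """
    if tau_c <= 0:
        raise ValueError(f"tau_c must be positive, got {tau_c}")
    if omega < 0:
        raise ValueError(f"omega must be non-negative, got {omega}")
    x = omega * tau_c
    return tau_c / (1.0 + x * x)


def _dipolar_prefactor(system: ParamagneticSystem, r: float) -> float:
    """(μ₀/4π)² γ_I² g_e² μ_B² S(S+1) / r⁶ — shared by Γ₁ and Γ₂."""
    if r <= 0:
        raise ValueError(f"r must be positive, got {r}")
    c = system.constants
    k = c.mu0 / (4.0 * math.pi)
    return (
        k * k
        * system.gamma_I ** 2
        * system.ge ** 2
        * c.muB ** 2
        * system.S * (system.S + 1.0)
        / r ** 6
    )


def pre_gamma1(system: ParamagneticSystem, r: float) -> float:
    """Longitudinal PRE Γ₁ (s⁻¹) at electron–nucleus distance ``r`` (m)."""
    tc = system.tau_c
    j = 3.0 * spectral_density(system.omega_I, tc) + 7.0 * spectral_density(
        system.omega_e, tc
    )
    return (2.0 / 15.0) * _dipolar_prefactor(system, r) * j


def pre_gamma2(system: ParamagneticSystem, r: float) -> float:
    """Transverse PRE Γ₂ (s⁻¹) at electron–nucleus distance ``r`` (m).

    The adiabatic 4τc term makes Γ₂ ≥ Γ₁ for every physical parameter set;
    equality holds only in the extreme-narrowing limit ω_e·τc ≪ 1.
    """
    tc = system.tau_c
    j = (
        4.0 * tc
        + 3.0 * spectral_density(system.omega_I, tc)
        + 13.0 * spectral_density(system.omega_e, tc)
    )
    return (1.0 / 15.0) * _dipolar_prefactor(system, r) * j


def predict(system: ParamagneticSystem, r: float) -> PREPrediction:
    """Convenience wrapper returning both rates at one distance."""
    return PREPrediction(pre_gamma1(system, r), pre_gamma2(system, r), r)


def nucleus_scaling_ratio(
    nucleus_a: str,
    nucleus_b: str,
    *,
    tau_c: float = 100e-12,
    B0: float = 14.09,
    S: float = 3.5,
    ge: float = CONSTANTS.ge_default,
    which: str = "gamma1",
) -> float:
    """Ratio Γ(nucleus_a)/Γ(nucleus_b) at identical r, τc, B0.

    In the regime ω_I²τc² ≪ 1 for both nuclei this reduces to the squared
    gyromagnetic-ratio ratio (γ_a/γ_b)², which is why ¹³C PREs are roughly
    (γ_C/γ_F)² ≈ 7 % of the ¹⁹F ones.
    """
    r = 10.0 * ANGSTROM  # cancels in the ratio
    fn = {"gamma1": pre_gamma1, "gamma2": pre_gamma2}[which]
    sys_a = ParamagneticSystem(S=S, ge=ge, tau_c=tau_c, nucleus=nucleus_a, B0=B0)
    sys_b = ParamagneticSystem(S=S, ge=ge, tau_c=tau_c, nucleus=nucleus_b, B0=B0)
    return fn(sys_a, r) / fn(sys_b, r)
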