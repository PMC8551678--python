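"""Conversions among atmospheric water potential, humidity and VPD.

Water vapor in equilibrium with air at relative humidity ``RH`` has the
(very negative) water potential

    psi_a = (R̄·T / v) · ln(RH),

with the gas constant ``R̄ = 8.3145 J·mol⁻¹·K⁻¹``, temperature ``T`` (K)
and the molar volume of liquid water ``v = 18·10⁻⁶ m³·mol⁻¹``.  The
vapor pressure deficit across the stomata is ``VPD = (1 − RH)·P`` with
``P`` the saturation vapor pressure (3.17 kPa at 298.15 K).

RH is a fraction in (0, 1] everywhere in this module; percentages
appear only at reporting boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GAS_CONSTANT",
    "ROOM_TEMPERATURE",
    "WATER_MOLAR_VOLUME",
    "SATURATION_VAPOR_PRESSURE_KPA",
    "AtmosphereSpec",
    "psi_from_rh",
    "rh_from_psi",
    "vpd_from_rh",
]

GAS_CONSTANT = 8.3145  # J·mol⁻¹·K⁻¹
ROOM_TEMPERATURE = 298.15  # K
WATER_MOLAR_VOLUME = 18e-6  # m³·mol⁻¹ of liquid water
SATURATION_VAPOR_PRESSURE_KPA = 3.17  # kPa at 298.15 K


def _scale_mpa(T: float) -> float:
    """R̄T/v in MPa."""
    return GAS_CONSTANT * T / WATER_MOLAR_VOLUME / 1e6


def psi_from_rh(rh: float, T: float = ROOM_TEMPERATURE) -> float:
    """Atmospheric water potential (MPa) of air at relative humidity ``rh``."""
    if not 0 < rh <= 1:
        raise ValueError(f"RH must be a fraction in (0, 1], got {rh}")
    return _scale_mpa(T) * math.log(rh)


def rh_from_psi(psi_a: float, T: float = ROOM_TEMPERATURE) -> float:
    """Relative humidity (fraction) of air at water potential ``psi_a`` MPa."""
    if psi_a > 0:
        raise ValueError(f"psi_a must be <= 0, got {psi_a}")
    return math.exp(psi_a / _scale_mpa(T))


def vpd_from_rh(rh: float, P: float = SATURATION_VAPOR_PRESSURE_KPA) -> float:
    """Vapor pressure deficit (kPa) of air at relative humidity ``rh``."""
    if not 0 < rh <= 1:
        raise ValueError(f"RH must be a fraction in (0, 1], got {rh}")
    if not P > 0:
        raise ValueError(f"P must be > 0, got {P}")
    return (1.0 - rh) * P


@dataclass(frozen=True)
class AtmosphereSpec:
    """A mutually consistent (psi_a, RH, VPD) triple at temperature T."""

    psi_a: float
    RH: float
    VPD: float
    T: float = ROOM_TEMPERATURE
    P: float = SATURATION_VAPOR_PRESSURE_KPA

    @classmethod
    def from_psi(
        cls,
        psi_a: float,
        T: float = ROOM_TEMPERATURE,
        P: float = SATURATION_VAPOR_PRESSURE_KPA,
    ) -> "AtmosphereSpec":
        rh = rh_from_psi(psi_a, T)
        return cls(psi_a=psi_a, RH=rh, VPD=vpd_from_rh(rh, P), T=T, P=P)

    @classmethod
    def from_rh(
        cls,
        rh: float,
        T: float = ROOM_TEMPERATURE,
        P: float = SATURATION_VAPOR_PRESSURE_KPA,
    ) -> "AtmosphereSpec":
        return cls(psi_a=psi_from_rh(rh, T), RH=rh, VPD=vpd_from_rh(rh, P), T=T, P=P)
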