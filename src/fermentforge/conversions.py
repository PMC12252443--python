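"""Oenological and gas-phase unit conversions.

The fermentation devices measure density in degrees Baumé and gas
concentrations in ppm; everything downstream works in g/L.  This module
collects the handful of conversions linking the two worlds:

* Baumé → specific gravity → sugar concentration (hydrometry of musts),
* gas-phase CO₂ ppm → g/L in air and, via Henry's law, g/L dissolved in
  fermenting wine,
* gas-phase ethanol ppm → liquid-equivalent mg/L through an ideal-gas
  molar volume and a gas/liquid partition coefficient,
* ethanol g/L → percent alcohol by volume.

All functions are pure, accept scalars or numpy arrays, and validate
their physical domains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EthanolConversionSettings",
    "CO2ConversionSettings",
    "baume_to_sg",
    "baume_to_sugar_gL",
    "co2_ppm_to_air_gL",
    "co2_ppm_to_dissolved_gL",
    "co2_partition_ratio",
    "ethanol_ppm_to_mgL",
    "ethanol_gL_to_vol_percent",
]

_ZERO_CELSIUS_K = 273.15


@dataclass(frozen=True)
class EthanolConversionSettings:
    """Physical constants for gas-phase ethanol conversion.

    ``partition_coeff_alpha`` is the equilibrium ratio of gas-phase to
    liquid-phase ethanol concentration; the default 2.5e-4 is the
    calibration value used by the probing-nose device.  Note that with
    this default, ppm-range gas readings map to liquid-equivalent
    concentrations far above typical must alcohol levels; the formula is
    applied literally and α is exposed so callers can recalibrate.
    """

    molar_mass: float = 46.07  # g/mol
    molar_volume_ref: float = 24.45  # L/mol at 25 °C, 1 atm
    reference_temp_K: float = 298.15
    partition_coeff_alpha: float = 2.5e-4
    density: float = 0.789  # g/mL at 20 °C

    def __post_init__(self) -> None:
        for name in (
            "molar_mass",
            "molar_volume_ref",
            "reference_temp_K",
            "partition_coeff_alpha",
            "density",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.partition_coeff_alpha > 1:
            raise ValueError("partition_coeff_alpha must be ≤ 1")


@dataclass(frozen=True)
class CO2ConversionSettings:
    """Physical constants for CO₂ gas/liquid conversion.

    ``henry_constant`` is Henry's constant for CO₂ in white wine
    (lower than in water); ``air_factor`` converts gas-phase ppm to g/L
    in air (it corresponds to an ideal-gas molar volume of 22.414 L/mol).
    """

    henry_constant: float = 1.65e-2  # mol/(L·atm)
    molar_mass: float = 44.01  # g/mol
    air_factor: float = 1.964e-6  # g/L per ppm in the gas phase
    partial_pressure: float = 1.0  # atm

    def __post_init__(self) -> None:
        for name in ("henry_constant", "molar_mass", "air_factor", "partial_pressure"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def dissolved_factor(self) -> float:
        """g/L dissolved in wine per ppm in the gas phase (Henry's law)."""
        return self.henry_constant * self.partial_pressure * self.molar_mass * 1e-6


def _check_nonnegative(x, name: str):
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr if arr.ndim else float(arr)


def baume_to_sg(baume):
    """Specific gravity of a must from its Baumé reading: SG = 145/(145−°Bé)."""
    b = np.asarray(baume, dtype=float)
    if np.any(b < 0) or np.any(b >= 145):
        raise ValueError("Baumé reading must lie in [0, 145)")
    sg = 145.0 / (145.0 - b)
    return sg if sg.ndim else float(sg)


def baume_to_sugar_gL(baume):
    """Sugar concentration (g/L) from Baumé via Brix ≈ 1.8·°Bé and SG.

    Sugar(g/L) = °Brix × SG × 10.
    """
    b = np.asarray(baume, dtype=float)
    out = 1.8 * b * np.asarray(baume_to_sg(b)) * 10.0
    return out if out.ndim else float(out)


def co2_ppm_to_air_gL(ppm, settings: CO2ConversionSettings = CO2ConversionSettings()):
    """Gas-phase CO₂ mass concentration (g/L in air) from a ppm reading."""
    p = _check_nonnegative(ppm, "ppm")
    return p * settings.air_factor


def co2_ppm_to_dissolved_gL(
    ppm, settings: CO2ConversionSettings = CO2ConversionSettings()
):
    """Dissolved CO₂ (g/L in wine) from a gas-phase ppm reading.

    Henry's law at the configured partial pressure: each ppm of gas-phase
    CO₂ corresponds to kH·P·M×1e-6 g/L in the liquid (7.262e-7 with the
    white-wine defaults).
    """
    p = _check_nonnegative(ppm, "ppm")
    return p * settings.dissolved_factor


def co2_partition_ratio(settings: CO2ConversionSettings = CO2ConversionSettings()) -> float:
    """Equilibrium ratio of dissolved to gas-phase CO₂ mass concentration.

    ≈ 0.37 with the defaults: fermenting white wine holds about 37 % of
    the gas-phase mass concentration in solution.
    """
    if settings.air_factor == 0:
        raise ValueError("air_factor must be non-zero")
    return settings.dissolved_factor / settings.air_factor


def ethanol_ppm_to_mgL(
    ppm,
    temp_C: float = 25.0,
    settings: EthanolConversionSettings = EthanolConversionSettings(),
):
    """Liquid-equivalent ethanol (mg/L) from a gas-phase ppm reading.

    C = ppm × M/Vm(T) × 1/α with the temperature-corrected molar volume
    Vm(T) = Vm_ref × T[K]/T_ref[K].
    """
    p = _check_nonnegative(ppm, "ppm")
    if temp_C <= -_ZERO_CELSIUS_K:
        raise ValueError("temperature below absolute zero")
    if settings.partition_coeff_alpha == 0:
        raise ValueError("partition coefficient must be non-zero")
    vm = settings.molar_volume_ref * ((temp_C + _ZERO_CELSIUS_K) / settings.reference_temp_K)
    return p * (settings.molar_mass / vm) / settings.partition_coeff_alpha


def ethanol_gL_to_vol_percent(
    conc_gL, settings: EthanolConversionSettings = EthanolConversionSettings()
):
    """Percent alcohol by volume from an ethanol mass concentration in g/L."""
    c = _check_nonnegative(conc_gL, "concentration")
    return c / (settings.density * 1000.0) * 100.0
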