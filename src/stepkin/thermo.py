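"""Closed-form thermodynamics of solution crystal growth.

This module collects the scalar relations used throughout the package:

* supersaturation (dimensionless driving force) ``Δμ/kBT = ln(C/Ce)``,
* van 't Hoff extraction of the crystallization enthalpy and entropy from
  the temperature dependence of the solubility ``Ce(T)``,
* interconversion between ``ΔG°``, ``(ΔH°, ΔS°)`` and ``Ce``,
* the equilibrium kink density of a restricted solid-on-solid step,
  ``n̄k⁻¹ = 2 / [exp(ω/kBT) + 2]``,
* the 2D-nucleation barrier and the step-train face growth rate
  ``R = h·v/l``.

Conventions
-----------
Energies are molar (J/mol) with the gas constant ``R``; conversion to
per-molecule quantities is internal.  Crystallization quantities (solution →
crystal) carry their natural negative signs: for a sparingly soluble solid
``ΔH° < 0`` and ``ΔG°(T) = RT·ln Ce < 0`` on the molarity scale with unit
activity coefficients.  Temperatures are kelvin unless converted explicitly
with :func:`kelvin`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .constants import N_AVOGADRO, R_GAS
from .errors import DomainError, InsufficientDataError

__all__ = [
    "SolubilityPoint",
    "ThermoParams",
    "Supersaturation",
    "KinkDensity",
    "NucleationInputs",
    "kelvin",
    "supersaturation",
    "fit_vant_hoff",
    "gibbs_from_solubility",
    "gibbs_from_hs",
    "solubility_from_thermo",
    "equilibrium_kink_density",
    "nucleation_barrier_2d",
    "face_growth_rate",
]

# Exponent guard for solubility_from_thermo: exp(50) ~ 5e21 mol/L is already
# unphysical by many orders of magnitude.
_MAX_EXPONENT = 50.0


def kelvin(value: float, unit: str = "K") -> float:
    """Convert a temperature to kelvin from an explicit unit tag.

    ``unit`` must be ``"K"`` or ``"C"``; there is deliberately no
    autodetection.
    """
    if unit == "K":
        t = float(value)
    elif unit == "C":
        t = float(value) + 273.15
    else:
        raise DomainError(f"unknown temperature unit {unit!r}; use 'K' or 'C'")
    if t <= 0:
        raise DomainError(f"temperature must be positive, got {t} K")
    return t


@dataclass(frozen=True)
class SolubilityPoint:
    """One equilibrium-solubility observation ``Ce`` at temperature ``T``."""

    temperature: float  # K
    solubility: float  # mol/L
    uncertainty: float | None = None  # mol/L, one standard deviation

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise DomainError(f"temperature must be > 0 K, got {self.temperature}")
        if self.solubility <= 0:
            raise DomainError(f"solubility must be > 0 mol/L, got {self.solubility}")
        if self.uncertainty is not None and self.uncertainty < 0:
            raise DomainError("uncertainty must be >= 0")


@dataclass(frozen=True)
class ThermoParams:
    """Crystallization enthalpy/entropy with regression standard errors.

    Sign convention: solution → crystal, so for theophylline in n-octanol
    both ``enthalpy`` and ``entropy`` are negative.
    """

    enthalpy: float  # J/mol  (ΔH°cryst)
    entropy: float  # J/mol/K (ΔS°cryst)
    enthalpy_se: float = 0.0
    entropy_se: float = 0.0
    reference_temperature: float = 298.15  # K
    n_points: int = 0
    r_squared: float = float("nan")
    residuals: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.enthalpy_se < 0 or self.entropy_se < 0:
            raise DomainError("standard errors must be >= 0")

    def gibbs(self, temperature: float | None = None) -> float:
        """ΔG°(T) = ΔH° − T·ΔS° in J/mol (defaults to the reference T)."""
        t = self.reference_temperature if temperature is None else temperature
        return gibbs_from_hs(self.enthalpy, self.entropy, t)

    def solubility(self, temperature: float | None = None) -> float:
        """Ce(T) implied by the fitted parameters, mol/L."""
        t = self.reference_temperature if temperature is None else temperature
        return solubility_from_thermo(self.enthalpy, self.entropy, t)


@dataclass(frozen=True)
class Supersaturation:
    """Solute concentration, equilibrium concentration and ln(C/Ce)."""

    concentration: float  # mol/L
    equilibrium_concentration: float  # mol/L
    dimensionless_driving_force: float  # Δμ/kBT

    @classmethod
    def from_concentrations(cls, concentration: float, equilibrium_concentration: float) -> "Supersaturation":
        return cls(
            concentration=concentration,
            equilibrium_concentration=equilibrium_concentration,
            dimensionless_driving_force=supersaturation(concentration, equilibrium_concentration),
        )


@dataclass(frozen=True)
class KinkDensity:
    """Equilibrium kink density at a given kink energy and temperature."""

    kink_energy: float  # J/mol (ω)
    temperature: float  # K
    density: float  # unitless, in (0, 2/3]

    @classmethod
    def at_equilibrium(cls, kink_energy: float, temperature: float) -> "KinkDensity":
        return cls(kink_energy, temperature, equilibrium_kink_density(kink_energy, temperature))


@dataclass(frozen=True)
class NucleationInputs:
    """Inputs of the 2D-nucleation barrier.

    ``edge_free_energy`` is an energy per unit step length (J/m); see
    :func:`nucleation_barrier_2d` for how this relates to a per-riser-area
    convention.  ``driving_force`` is molar (J/mol), consistent with the
    package-wide energy convention.
    """

    molecular_volume: float  # A^3 (Ω)
    layer_thickness: float  # nm (h)
    edge_free_energy: float  # J/m (γ)
    driving_force: float  # J/mol (Δμ)

    def __post_init__(self) -> None:
        for name in ("molecular_volume", "layer_thickness", "edge_free_energy", "driving_force"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive")


def supersaturation(concentration: float, equilibrium_concentration: float) -> float:
    """Dimensionless driving force Δμ/kBT = ln(C/Ce).

    Negative for undersaturation, zero at equilibrium.
    """
    if concentration <= 0:
        raise DomainError(f"concentration must be > 0, got {concentration}")
    if equilibrium_concentration <= 0:
        raise DomainError(
            f"equilibrium_concentration must be > 0, got {equilibrium_concentration}"
        )
    return math.log(concentration / equilibrium_concentration)


def _linear_fit(x: np.ndarray, y: np.ndarray, weights: np.ndarray | None):
    """Weighted least squares of y on x; returns slope, intercept, SEs, R², residuals.

    For two points the line is exact and the standard errors are reported
    as zero (no residual degrees of freedom).
    """
    n = x.size
    w = np.ones_like(x) if weights is None else weights
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    if sxx <= 0:
        raise InsufficientDataError("regressor values are all identical")
    slope = (w * (x - xm) * (y - ym)).sum() / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    rss = float((w * resid**2).sum())
    tss = float((w * (y - ym) ** 2).sum())
    r2 = 1.0 if tss == 0 else 1.0 - rss / tss
    if n > 2:
        s2 = rss / (n - 2)
        slope_se = math.sqrt(s2 / sxx)
        intercept_se = math.sqrt(s2 * (1.0 / sw + xm**2 / sxx))
    else:
        slope_se = intercept_se = 0.0
    return slope, intercept, slope_se, intercept_se, r2, resid


def fit_vant_hoff(
    points: Iterable[SolubilityPoint],
    weighted: bool = False,
    reference_temperature: float = 298.15,
) -> ThermoParams:
    """Fit ln Ce against 1/T and return (ΔH°, ΔS°) with standard errors.

    van 't Hoff's law for the crystallization equilibrium ``Kcryst = Ce⁻¹``
    gives ``∂lnCe/∂(1/T) = ΔH°cryst/R`` so the slope of ln Ce on 1/T is
    ``ΔH°/R`` and the intercept is ``−ΔS°/R`` (from
    ``RT ln Ce = ΔG° = ΔH° − TΔS°``).

    Parameters
    ----------
    points:
        At least two :class:`SolubilityPoint` at distinct temperatures.
    weighted:
        When true, use inverse-variance weights derived from the per-point
        uncertainties (propagated to ln Ce).  All points must then carry a
        positive ``uncertainty``.
    """
    pts = list(points)
    temps = {p.temperature for p in pts}
    if len(temps) < 2:
        raise InsufficientDataError(
            f"need >= 2 points at distinct temperatures, got {len(temps)}"
        )
    x = np.array([1.0 / p.temperature for p in pts])
    y = np.array([math.log(p.solubility) for p in pts])
    weights = None
    if weighted:
        if any(p.uncertainty is None or p.uncertainty <= 0 for p in pts):
            raise InsufficientDataError(
                "weighted fit requires a positive uncertainty on every point"
            )
        sigma_lnc = np.array([p.uncertainty / p.solubility for p in pts])
        weights = 1.0 / sigma_lnc**2
    slope, intercept, slope_se, intercept_se, r2, resid = _linear_fit(x, y, weights)
    return ThermoParams(
        enthalpy=R_GAS * slope,
        entropy=-R_GAS * intercept,
        enthalpy_se=R_GAS * slope_se,
        entropy_se=R_GAS * intercept_se,
        reference_temperature=reference_temperature,
        n_points=len(pts),
        r_squared=r2,
        residuals=tuple(float(r) for r in resid),
    )


def gibbs_from_solubility(equilibrium_concentration: float, temperature: float) -> float:
    """ΔG°cryst = −RT ln Kcryst = RT ln Ce, in J/mol.

    ``Ce`` on the molarity scale with unit activity coefficients: for
    Ce < 1 M the result is negative, as expected for spontaneous
    crystallization from a saturated solution.
    """
    if equilibrium_concentration <= 0:
        raise DomainError(
            f"equilibrium_concentration must be > 0, got {equilibrium_concentration}"
        )
    if temperature <= 0:
        raise DomainError(f"temperature must be > 0 K, got {temperature}")
    return R_GAS * temperature * math.log(equilibrium_concentration)


def gibbs_from_hs(enthalpy: float, entropy: float, temperature: float) -> float:
    """ΔG°(T) = ΔH° − T·ΔS°, all molar."""
    if temperature <= 0:
        raise DomainError(f"temperature must be > 0 K, got {temperature}")
    return enthalpy - temperature * entropy


def solubility_from_thermo(enthalpy: float, entropy: float, temperature: float) -> float:
    """Invert :func:`gibbs_from_solubility`: Ce = exp[ΔG°/(RT)] in mol/L."""
    if temperature <= 0:
        raise DomainError(f"temperature must be > 0 K, got {temperature}")
    exponent = gibbs_from_hs(enthalpy, entropy, temperature) / (R_GAS * temperature)
    if exponent > _MAX_EXPONENT:
        raise DomainError(
            f"ΔG/(RT) = {exponent:.1f} exceeds the overflow guard ({_MAX_EXPONENT})"
        )
    return math.exp(exponent)


def equilibrium_kink_density(kink_energy: float, temperature: float) -> float:
    """Equilibrium kink density of a restricted solid-on-solid step.

    ``n̄k⁻¹ = 2 / [exp(ω/kBT) + 2]`` with ω molar (J/mol) so the Boltzmann
    factor uses RT.  The value lies in (0, 2/3]: at ω = 0 each of the three
    allowed height differences {−1, 0, +1} between neighboring edge sites is
    equally likely and two of the three are kinks.
    """
    if kink_energy < 0:
        raise DomainError(f"kink_energy must be >= 0, got {kink_energy}")
    if temperature <= 0:
        raise DomainError(f"temperature must be > 0 K, got {temperature}")
    return 2.0 / (math.exp(kink_energy / (R_GAS * temperature)) + 2.0)


def nucleation_barrier_2d(inputs: NucleationInputs) -> float:
    """Free-energy barrier for 2D nucleation of a new layer, in J per nucleus.

    Implemented as the classical disk-nucleus result

        ``ΔG*₂D = π·Ω·γ² / (h·Δμ)``   (Δμ per molecule),

    where Ω is the molecular volume, h the layer thickness and γ the edge
    free energy per unit step *length* (J/m).  When γ is instead quoted per
    unit riser *area* (γ_area = γ/h), the same barrier reads
    ``π·Ω·h·γ_area²/Δμ`` — the form often quoted; the two conventions
    differ only by the placement of h.  The molar ``driving_force`` is
    converted to per-molecule internally.
    """
    omega_m3 = inputs.molecular_volume * 1e-30
    h_m = inputs.layer_thickness * 1e-9
    dmu_molec = inputs.driving_force / N_AVOGADRO
    return math.pi * omega_m3 * inputs.edge_free_energy**2 / (h_m * dmu_molec)


def face_growth_rate(step_height_nm: float, step_velocity_nm_s: float, step_spacing_nm: float) -> float:
    """Normal face growth rate of a step train, R = h·v/l, in nm/s."""
    if step_height_nm <= 0:
        raise DomainError(f"step height must be > 0, got {step_height_nm}")
    if step_spacing_nm <= 0:
        raise DomainError(f"step spacing must be > 0, got {step_spacing_nm}")
    return step_height_nm * step_velocity_nm_s / step_spacing_nm


def restricted_sos_kink_density_enumeration(
    kink_energy: float, temperature: float
) -> float:
    """Brute-force check of the restricted-SOS kink density.

    Enumerates the three allowed height differences d ∈ {−1, 0, +1} with
    Boltzmann weight exp(−ω|d|/RT) and returns the probability that d ≠ 0.
    Kept here (not in tests) because it doubles as documentation of why the
    denominator is exp(ω/kBT) + 2.
    """
    beta_omega = kink_energy / (R_GAS * temperature)
    weights = {d: math.exp(-beta_omega * abs(d)) for d in (-1, 0, 1)}
    z = sum(weights.values())
    return (weights[-1] + weights[1]) / z
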