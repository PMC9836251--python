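"""Stefan–Boltzmann radiometry of a skin ROI and delta-method error propagation.

Infrared thermography (IRT) detects brown adipose tissue (BAT) through the
heat power radiated by the overlying skin region of interest (ROI).  The
power reaching the camera from an ROI of area ``A``, temperature ``T`` and
emissivity ``eps`` follows the Stefan–Boltzmann law

    E = sigma * eps * A * T**4

with ``sigma`` the Stefan constant.  Two measured quantities carry error:
the operator-delineated ROI area and the temperature readout.  Treating the
two as independent (zero covariance), the first-order (delta-method)
propagation of their errors ``dA`` and ``dT`` to the power is

    Var(E) = (dE/dA)**2 * dA**2 + (dE/dT)**2 * dT**2
           = sigma**2 * eps**2 * (T**8 * dA**2 + 16 * A**2 * T**6 * dT**2)

This module provides the power, its partial derivatives, and the propagated
variance with its two components kept separate, so downstream code can ask
which error source dominates.

Units
-----
Areas are carried in cm^2 at every interface (the convention of the field's
published ROI sizes); conversion to m^2 happens only where absolute power in
watts is formed.  Temperatures are kelvin.  Error magnitudes are one
standard deviation of the stated distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "STEFAN_BOLTZMANN",
    "SKIN_EMISSIVITY",
    "CM2_PER_M2",
    "RadiativeSurface",
    "ErrorModel",
    "ErrorBudget",
    "radiative_power",
    "partial_wrt_area",
    "partial_wrt_temperature",
    "propagate_error",
]

# Stefan constant as used throughout the analysis this package implements
# (2 significant figures); CODATA value is 5.670374419e-8 W m^-2 K^-4.
STEFAN_BOLTZMANN: float = 5.6e-8  # W m^-2 K^-4

#: Default emissivity of human skin (dimensionless, long-wave infrared).
SKIN_EMISSIVITY: float = 0.98

CM2_PER_M2: float = 1.0e4


@dataclass(frozen=True)
class RadiativeSurface:
    """The measured quantities entering the Stefan–Boltzmann law.

    Parameters
    ----------
    area_cm2:
        ROI area in cm^2.  Must be non-negative.
    temperature_K:
        Temperature entering the fourth-power law, in kelvin.  Depending on
        context this is either the absolute skin temperature or the
        activation temperature rise; the formulas are agnostic.
    emissivity:
        Dimensionless emissivity in [0, 1]; defaults to typical human skin.
    """

    area_cm2: float
    temperature_K: float
    emissivity: float = SKIN_EMISSIVITY

    def __post_init__(self) -> None:
        if not (self.area_cm2 >= 0.0):
            raise ValueError(f"area_cm2 must be >= 0, got {self.area_cm2}")
        if not (self.temperature_K >= 0.0):
            raise ValueError(
                f"temperature_K must be >= 0, got {self.temperature_K}"
            )
        if not (0.0 <= self.emissivity <= 1.0):
            raise ValueError(
                f"emissivity must be in [0, 1], got {self.emissivity}"
            )

    @property
    def area_m2(self) -> float:
        return self.area_cm2 / CM2_PER_M2


@dataclass(frozen=True)
class ErrorModel:
    """Error magnitudes for the ROI area and the temperature readout.

    Magnitudes are one standard deviation.  ``distribution`` selects the
    error family used when samples are drawn (Monte Carlo paths); the
    analytic propagation only uses the standard deviations and is therefore
    distribution-free to first order.
    """

    delta_area_cm2: float = 10.0
    delta_temperature_K: float = 0.01
    distribution: str = "gaussian"

    def __post_init__(self) -> None:
        if self.delta_area_cm2 < 0.0:
            raise ValueError("delta_area_cm2 must be >= 0")
        if self.delta_temperature_K < 0.0:
            raise ValueError("delta_temperature_K must be >= 0")
        if self.distribution not in ("gaussian", "uniform"):
            raise ValueError(
                "distribution must be 'gaussian' or 'uniform', "
                f"got {self.distribution!r}"
            )

    def sample_area(self, rng, mean_cm2: float, n: int):
        """Draw ``n`` area samples centred on ``mean_cm2`` (cm^2)."""
        return _draw(rng, mean_cm2, self.delta_area_cm2, n, self.distribution)

    def sample_temperature(self, rng, mean_K: float, n: int):
        """Draw ``n`` temperature samples centred on ``mean_K`` (K)."""
        return _draw(rng, mean_K, self.delta_temperature_K, n, self.distribution)


def _draw(rng, mean: float, sd: float, n: int, distribution: str):
    if distribution == "gaussian":
        return rng.normal(mean, sd, size=n)
    # uniform with the requested standard deviation: half-width sqrt(3)*sd
    half = math.sqrt(3.0) * sd
    return rng.uniform(mean - half, mean + half, size=n)


@dataclass(frozen=True)
class ErrorBudget:
    """Propagated variance of the radiative power, split by error source.

    ``component_area`` and ``component_temperature`` are the two bracketed
    terms of the propagated variance, ``T**8 * dA**2`` and
    ``16 * A**2 * T**6 * dT**2``, evaluated in SI units (m^2) so that

        variance_total == sigma**2 * eps**2 * (component_area
                                               + component_temperature)

    holds exactly, with ``variance_total`` in W^2.  Their quotient ``ratio``
    is unit-free (area enters only through dA/A) and identical to the same
    ratio formed in cm^2.
    """

    variance_total: float
    component_area: float
    component_temperature: float
    ratio: float
    dominance: str

    @property
    def std_total(self) -> float:
        return math.sqrt(self.variance_total)


def radiative_power(surface: RadiativeSurface) -> float:
    """Radiated heat power E = sigma * eps * A * T**4, in watts.

    Strictly increasing in each of area, temperature and emissivity.
    """
    return (
        STEFAN_BOLTZMANN
        * surface.emissivity
        * surface.area_m2
        * surface.temperature_K**4
    )


def partial_wrt_area(surface: RadiativeSurface) -> float:
    """dE/dA = sigma * eps * T**4, in W per m^2 of ROI area.

    Independent of the area itself.
    """
    return STEFAN_BOLTZMANN * surface.emissivity * surface.temperature_K**4


def partial_wrt_temperature(surface: RadiativeSurface) -> float:
    """dE/dT = 4 * sigma * eps * A * T**3, in W per kelvin."""
    return (
        4.0
        * STEFAN_BOLTZMANN
        * surface.emissivity
        * surface.area_m2
        * surface.temperature_K**3
    )


def dominance_label(ratio: float, band: float = 0.0) -> str:
    """Classify an area/temperature error ratio.

    ``area`` when ratio > 1 + band, ``temperature`` when ratio < 1 - band,
    ``comparable`` otherwise (including an undefined ratio from two zero
    components).
    """
    if math.isnan(ratio):
        return "comparable"
    # small relative guard so the exact crossover classifies as comparable
    # despite floating-point noise in the ratio
    eps = 1e-9
    if ratio > (1.0 + band) * (1.0 + eps):
        return "area"
    if ratio < (1.0 - band) * (1.0 - eps):
        return "temperature"
    return "comparable"


def propagate_error(
    surface: RadiativeSurface,
    errors: ErrorModel,
    band: float = 0.0,
) -> ErrorBudget:
    """First-order propagated variance of the radiative power.

    The covariance term vanishes because area-delineation and temperature
    errors are independent.  Components are stored separately so the
    dominant error source can be read off; see :class:`ErrorBudget` for the
    unit conventions.
    """
    a_m2 = surface.area_m2
    da_m2 = errors.delta_area_cm2 / CM2_PER_M2
    t = surface.temperature_K
    dt = errors.delta_temperature_K

    comp_area = t**8 * da_m2**2
    comp_temp = 16.0 * a_m2**2 * t**6 * dt**2
    prefactor = (STEFAN_BOLTZMANN * surface.emissivity) ** 2
    variance_total = prefactor * (comp_area + comp_temp)

    if comp_temp > 0.0:
        ratio = comp_area / comp_temp
    elif comp_area > 0.0:
        ratio = math.inf
    else:
        ratio = math.nan

    return ErrorBudget(
        variance_total=variance_total,
        component_area=comp_area,
        component_temperature=comp_temp,
        ratio=ratio,
        dominance=dominance_label(ratio, band),
    )
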