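"""Analytic error budget: components, the error ratio rho, and crossovers.

Comparing the two terms of the propagated variance of the Stefan–Boltzmann
power isolates which measurement error dominates IRT-based BAT detection.
With area in cm^2 (the convention of published ROI sizes) the components are

    eps_A = T**8 * dA**2            (ROI-area error contribution)
    eps_T = 16 * A**2 * T**6 * dT**2  (temperature error contribution)

and their quotient, the error ratio,

    rho = eps_A / eps_T = T**2 * dA**2 / (16 * dT**2 * A**2)

is dimensionless (area enters only through dA/A).  For the reference
temperature error dT = 0.01 K this is 625 * T**2 * (dA/A)**2.  rho > 1 means
ROI-area uncertainty dominates; rho < 1 means temperature uncertainty
dominates.  The crossover area where the two contributions are equal is

    A* = T * dA / (4 * dT)

so with dA = 10 cm^2, dT = 0.01 K the crossover sits at 375 cm^2 for a
1.5 K activation rise and at 50 cm^2 for a 0.2 K rise — small (neonatal)
ROIs are area-error dominated, very large ROIs temperature-error dominated.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

from .radiometry import ErrorModel, dominance_label

__all__ = [
    "NoCrossoverError",
    "DominanceResult",
    "error_components",
    "error_ratio",
    "crossover_area",
    "ratio_bounds",
    "classify_dominance",
]


class NoCrossoverError(ValueError):
    """Raised when rho(A) = 1 has no positive solution (dT or dA zero)."""


@dataclass(frozen=True)
class DominanceResult:
    """Error-ratio classification at one (A, T) operating point."""

    area_cm2: float
    temp_K: float
    delta_area_cm2: float
    delta_temp_K: float
    rho: float
    crossover_cm2: float
    dominance: str

    def to_dict(self) -> dict:
        return asdict(self)


def _check_positive(area_cm2: float, temperature_K: float) -> None:
    if not (area_cm2 > 0.0):
        raise ValueError(f"area must be > 0, got {area_cm2}")
    if not (temperature_K > 0.0):
        raise ValueError(f"temperature must be > 0, got {temperature_K}")


def error_components(
    area_cm2: float, temperature_K: float, errors: ErrorModel
) -> tuple[float, float]:
    """The two variance components (eps_A, eps_T) in cm^2-based units.

    These are the bracketed terms of the propagated variance before the
    common sigma^2 * eps^2 prefactor; only their ratio is used downstream,
    which is unit-convention free.
    """
    _check_positive(area_cm2, temperature_K)
    eps_a = temperature_K**8 * errors.delta_area_cm2**2
    eps_t = (
        16.0
        * area_cm2**2
        * temperature_K**6
        * errors.delta_temperature_K**2
    )
    return eps_a, eps_t


def error_ratio(
    area_cm2: float,
    temperature_K: float,
    errors: ErrorModel,
    on_unbounded: str = "inf",
) -> float:
    """Error ratio rho = T**2 * dA**2 / (16 * dT**2 * A**2).

    With dT = 0 the ratio is unbounded: ``on_unbounded`` selects between
    returning ``math.inf`` (default) and raising ``ZeroDivisionError``.
    """
    _check_positive(area_cm2, temperature_K)
    if errors.delta_temperature_K == 0.0:
        if on_unbounded == "inf":
            return math.inf
        raise ZeroDivisionError("delta_temperature_K = 0: rho is unbounded")
    return (
        temperature_K**2
        * errors.delta_area_cm2**2
        / (16.0 * errors.delta_temperature_K**2 * area_cm2**2)
    )


def crossover_area(temperature_K: float, errors: ErrorModel) -> float:
    """Area A* (cm^2) where the two error contributions are equal.

    Closed form A* = T * dA / (4 * dT), the unique positive root of
    rho(A) = 1; rho > 1 (area-dominated) for A < A*, rho < 1 for A > A*.
    """
    if not (temperature_K > 0.0):
        raise ValueError(f"temperature must be > 0, got {temperature_K}")
    if errors.delta_temperature_K == 0.0 or errors.delta_area_cm2 == 0.0:
        raise NoCrossoverError(
            "rho(A) = 1 has no solution when delta_area or delta_temperature "
            "is zero"
        )
    return (
        temperature_K
        * errors.delta_area_cm2
        / (4.0 * errors.delta_temperature_K)
    )


def ratio_bounds(
    t_low_K: float, t_high_K: float, errors: ErrorModel
) -> tuple[float, float]:
    """Bounds on rho over a temperature interval, as multipliers of (dA/A)**2.

    Since rho = (T**2 / (16 dT**2)) * (dA/A)**2 is increasing in T, over
    T in [t_low, t_high] the coefficient ranges over
    (t_low**2 / (16 dT**2), t_high**2 / (16 dT**2)).  At dT = 0.01 K and
    T in [0.2, 1.5] this evaluates to (25, 1406.25).
    """
    if not (0.0 < t_low_K <= t_high_K):
        raise ValueError("require 0 < t_low_K <= t_high_K")
    if errors.delta_temperature_K == 0.0:
        raise ZeroDivisionError("delta_temperature_K = 0: bounds are unbounded")
    denom = 16.0 * errors.delta_temperature_K**2
    return t_low_K**2 / denom, t_high_K**2 / denom


def classify_dominance(
    area_cm2: float,
    temperature_K: float,
    errors: ErrorModel,
    band: float = 0.0,
) -> DominanceResult:
    """Classify the dominant error source at an (A, T) operating point.

    ``band`` widens the "comparable" verdict to 1 - band < rho < 1 + band;
    the default band of 0 gives the strict binary split.
    """
    rho = error_ratio(area_cm2, temperature_K, errors)
    try:
        a_star = crossover_area(temperature_K, errors)
    except NoCrossoverError:
        a_star = math.nan
    return DominanceResult(
        area_cm2=area_cm2,
        temp_K=temperature_K,
        delta_area_cm2=errors.delta_area_cm2,
        delta_temp_K=errors.delta_temperature_K,
        rho=rho,
        crossover_cm2=a_star,
        dominance=dominance_label(rho, band),
    )
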