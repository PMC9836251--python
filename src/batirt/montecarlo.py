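"""Monte Carlo conditional-variance ratio grid for the Stefan–Boltzmann model.

An independent, simulation-based check of the analytic error budget: perturb
the ROI area and the temperature with Gaussian errors,

    A_s ~ N(A, sigma_A**2),   T_s ~ N(T, sigma_T**2),

and compare the variance each induces in the radiative power E = c * A * T**4
through the log conditional-variance ratio

    rho(A, T) = ln( A**2 * Var(T_s**4) / ( T**8 * Var(A_s) ) )

(the constant c cancels).  rho > 0 means the temperature-error contribution
to Var(E) exceeds the area-error contribution; rho < 0 means ROI-area error
dominates.  Scanning rho over a lattice of (A, T) values maps the dominance
boundary across the physiological range of BAT ROI areas (~1–400 cm^2) and
activation temperature rises (~0.1–1.5 K).

Because T_s**4 is a polynomial in a Gaussian variable, Var(T_s**4) has an
exact central-moment closed form; :func:`exact_log_ratio` uses it as the
deterministic counterpart of the sampled estimate, and in the small-noise
limit reduces to the linearization ln(16 A**2 sigma_T**2 / (T**2 sigma_A**2))
— the same algebra (with signs and logs rearranged) as the analytic error
ratio.

Default error magnitudes are sigma_A = 10 cm^2 and sigma_T = 0.02 K.  The
temperature sigma is deliberately the grid-calibration value (within the
0.005–0.05 K thermal-sensitivity range of IRT cameras) that reproduces the
reference grid this scan is compared against; the analytic budget module
defaults to dT = 0.01 K instead.  See docs/methods.md.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_AREA_GRID",
    "DEFAULT_TEMP_GRID",
    "DegenerateSampleError",
    "MCConfig",
    "VarianceRatioGrid",
    "mc_variance_ratio",
    "exact_var_fourth_power",
    "exact_log_ratio",
    "grid_scan",
    "dominance_boundary",
]

#: Reference area lattice (cm^2): 1, then 20..400 in steps of 20 (21 rows).
DEFAULT_AREA_GRID: tuple[float, ...] = (1.0,) + tuple(
    float(a) for a in range(20, 401, 20)
)

#: Reference temperature lattice (K): 0.1..1.5 in steps of 0.1 (15 columns).
DEFAULT_TEMP_GRID: tuple[float, ...] = tuple(
    round(0.1 * k, 1) for k in range(1, 16)
)


class DegenerateSampleError(RuntimeError):
    """Raised when a sample variance needed in the ratio is zero."""


@dataclass(frozen=True)
class MCConfig:
    """Configuration of a Monte Carlo variance-ratio grid scan.

    ``use_exact_area_variance`` substitutes sigma_A**2 for the sampled
    Var(A_s) (both are estimates of the same quantity; sampling both mirrors
    the simulation as stated, substitution removes one noise source).
    """

    area_grid: Sequence[float] = DEFAULT_AREA_GRID
    temp_grid: Sequence[float] = DEFAULT_TEMP_GRID
    sigma_area: float = 10.0
    sigma_temp: float = 0.02
    n_samples: int = 1_000_000
    seed: int = 0
    distribution: str = "gaussian"
    use_exact_area_variance: bool = False

    def __post_init__(self) -> None:
        for name in ("area_grid", "temp_grid"):
            grid = np.asarray(getattr(self, name), dtype=float)
            if grid.size == 0:
                raise ValueError(f"{name} must be non-empty")
            if grid.size > 1 and not np.all(np.diff(grid) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        if self.sigma_area < 0 or self.sigma_temp < 0:
            raise ValueError("sigma values must be >= 0")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        if self.distribution not in ("gaussian", "uniform"):
            raise ValueError("distribution must be 'gaussian' or 'uniform'")

    def to_dict(self) -> dict:
        return {
            "area_grid": [float(a) for a in self.area_grid],
            "temp_grid": [float(t) for t in self.temp_grid],
            "sigma_area": self.sigma_area,
            "sigma_temp": self.sigma_temp,
            "n_samples": self.n_samples,
            "seed": self.seed,
            "distribution": self.distribution,
            "use_exact_area_variance": self.use_exact_area_variance,
        }


def _log_variance_se(samples: np.ndarray, variance: float) -> float:
    # delta method: Var(ln Vhat) ~ (kappa - 1)/n, kappa the kurtosis of the
    # summand; reduces to 2/n for Gaussian samples.
    centered = samples - samples.mean()
    kappa = float(np.mean(centered**4)) / variance**2
    return math.sqrt(max(kappa - 1.0, 0.0) / samples.size)


def mc_variance_ratio(
    area: float,
    temp: float,
    sigma_area: float = 10.0,
    sigma_temp: float = 0.02,
    n_samples: int = 1_000_000,
    seed: int | np.random.SeedSequence = 0,
    distribution: str = "gaussian",
    use_exact_area_variance: bool = False,
    return_se: bool = False,
):
    """Sampled log conditional-variance ratio at one (A, T) point.

    Draws ``n_samples`` of each of A_s and T_s, forms unbiased (n-1) sample
    variances, and returns ln(A**2 Var(T_s**4) / (T**8 Var(A_s))) in natural
    log.  With ``return_se`` also returns a delta-method standard error of
    the estimate (both variance estimators contribute; the area term is
    dropped when its variance is substituted exactly).
    """
    if not (area > 0 and temp > 0):
        raise ValueError("area and temp must be > 0")
    if sigma_temp <= 0 or sigma_area <= 0:
        raise ValueError("sigma_area and sigma_temp must be > 0")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")

    rng = np.random.default_rng(seed)
    if distribution == "gaussian":
        t_s = rng.normal(temp, sigma_temp, size=n_samples)
        a_s = rng.normal(area, sigma_area, size=n_samples)
    else:
        half_t = math.sqrt(3.0) * sigma_temp
        half_a = math.sqrt(3.0) * sigma_area
        t_s = rng.uniform(temp - half_t, temp + half_t, size=n_samples)
        a_s = rng.uniform(area - half_a, area + half_a, size=n_samples)

    t4 = t_s**4
    var_t4 = float(np.var(t4, ddof=1))
    if use_exact_area_variance:
        var_a = sigma_area**2
    else:
        var_a = float(np.var(a_s, ddof=1))
    if var_t4 == 0.0 or var_a == 0.0:
        raise DegenerateSampleError(
            f"degenerate sample variance at (A={area}, T={temp})"
        )

    rho = math.log(area**2 * var_t4 / (temp**8 * var_a))
    if not return_se:
        return rho
    se_sq = _log_variance_se(t4, var_t4) ** 2
    if not use_exact_area_variance:
        se_sq += _log_variance_se(a_s, var_a) ** 2
    return rho, math.sqrt(se_sq)


def exact_var_fourth_power(mu: float, sigma: float) -> float:
    """Exact Var(X**4) for X ~ N(mu, sigma**2).

    From the Gaussian moment expansions
    E[X**4] = mu**4 + 6 mu**2 s**2 + 3 s**4 and
    E[X**8] = mu**8 + 28 mu**6 s**2 + 210 mu**4 s**4 + 420 mu**2 s**6
              + 105 s**8,
    the difference E[X**8] - E[X**4]**2 collapses to the all-positive form

        Var(X**4) = 16 mu**6 s**2 + 168 mu**4 s**4 + 384 mu**2 s**6
                    + 96 s**8

    which is evaluated directly (no catastrophic cancellation at small
    sigma).  The small-sigma limit is 16 mu**6 sigma**2.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    s2 = sigma**2
    m2 = mu**2
    return s2 * (
        16.0 * m2**3 + 168.0 * m2**2 * s2 + 384.0 * m2 * s2**2 + 96.0 * s2**3
    )


def exact_log_ratio(
    area: float, temp: float, sigma_area: float, sigma_temp: float
) -> float:
    """Deterministic counterpart of :func:`mc_variance_ratio`.

    ln(A**2 * Var(T_s**4) / (T**8 * sigma_A**2)) with the exact Gaussian
    moment formula for Var(T_s**4); reduces to
    ln(16 A**2 sigma_T**2 / (T**2 sigma_A**2)) as sigma_T/T -> 0.
    """
    if not (area > 0 and temp > 0 and sigma_area > 0 and sigma_temp > 0):
        raise ValueError("all arguments must be > 0")
    return math.log(
        area**2
        * exact_var_fourth_power(temp, sigma_temp)
        / (temp**8 * sigma_area**2)
    )


@dataclass
class VarianceRatioGrid:
    """rho(A, T) over an (A, T) lattice, with sign map and dominance boundary.

    ``values[i, j]`` is rho at ``area_grid[i]``, ``temp_grid[j]``.
    ``boundary[j]`` is the interpolated area (cm^2) at which rho changes
    sign in column j, NaN when the column has no sign change within the
    lattice.
    """

    values: np.ndarray
    config: MCConfig
    standard_errors: np.ndarray | None = None
    sign_map: np.ndarray = field(init=False)
    boundary: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.config.area_grid), len(self.config.temp_grid))
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} does not match grids "
                f"{expected}"
            )
        self.sign_map = np.sign(self.values).astype(int)
        self.boundary = dominance_boundary(self)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(list(self.config.area_grid), name="A"),
            columns=pd.Index(list(self.config.temp_grid), name="T"),
        )

    def boundary_summary(self) -> tuple[float, float]:
        """(min, max) of the dominance boundary over the columns with one."""
        finite = self.boundary[np.isfinite(self.boundary)]
        if finite.size == 0:
            return math.nan, math.nan
        return float(finite.min()), float(finite.max())

    def to_csv(self, path: str | Path) -> None:
        """Write the grid in reference layout: A labels down the first
        column, T values across the header, cells to 6 decimals."""
        df = self.to_dataframe()
        df.index = pd.Index([f"{a:g}" for a in df.index], name="A")
        df.columns = pd.Index([f"{t:g}" for t in df.columns], name="T")
        df.to_csv(path, float_format="%.6f")

    def to_json(self, path: str | Path) -> None:
        bmin, bmax = self.boundary_summary()
        payload = {
            "config": self.config.to_dict(),
            "boundary_cm2": [
                None if math.isnan(b) else float(b) for b in self.boundary
            ],
            "boundary_min_cm2": None if math.isnan(bmin) else bmin,
            "boundary_max_cm2": None if math.isnan(bmax) else bmax,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def grid_scan(config: MCConfig) -> VarianceRatioGrid:
    """Evaluate the sampled log variance ratio at every lattice point.

    Each cell uses an independent RNG substream keyed by (seed, row,
    column), so the grid is bitwise reproducible and independent of the
    evaluation order.
    """
    n_a, n_t = len(config.area_grid), len(config.temp_grid)
    values = np.empty((n_a, n_t))
    ses = np.empty((n_a, n_t))
    for i, a in enumerate(config.area_grid):
        for j, t in enumerate(config.temp_grid):
            try:
                values[i, j], ses[i, j] = mc_variance_ratio(
                    float(a),
                    float(t),
                    sigma_area=config.sigma_area,
                    sigma_temp=config.sigma_temp,
                    n_samples=config.n_samples,
                    seed=np.random.SeedSequence([config.seed, i, j]),
                    distribution=config.distribution,
                    use_exact_area_variance=config.use_exact_area_variance,
                    return_se=True,
                )
            except (ValueError, DegenerateSampleError) as exc:
                raise type(exc)(
                    f"grid cell (A={a}, T={t}) [row {i}, col {j}]: {exc}"
                ) from exc
    return VarianceRatioGrid(values=values, config=config, standard_errors=ses)


def dominance_boundary(grid: VarianceRatioGrid) -> np.ndarray:
    """Per-temperature area of sign change, linearly interpolated.

    rho increases with A along each column, so the boundary is where the
    column crosses zero going negative -> positive.  Columns entirely of one
    sign get NaN (boundary outside the lattice).  In the linearized regime
    the boundary follows A(T) = (sigma_A / (4 sigma_T)) * T.
    """
    areas = np.asarray(grid.config.area_grid, dtype=float)
    n_t = len(grid.config.temp_grid)
    boundary = np.full(n_t, np.nan)
    for j in range(n_t):
        col = grid.values[:, j]
        crossings = np.nonzero((col[:-1] < 0) & (col[1:] >= 0))[0]
        if crossings.size == 0:
            continue
        i = int(crossings[0])
        v0, v1 = col[i], col[i + 1]
        if v1 == v0:
            boundary[j] = areas[i]
        else:
            boundary[j] = areas[i] + (0.0 - v0) / (v1 - v0) * (
                areas[i + 1] - areas[i]
            )
    return boundary
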