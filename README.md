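# batirt

Uncertainty analysis of infrared-thermography (IRT) detection of brown
adipose tissue (BAT).

IRT is an attractive, radiation-free alternative to PET-CT for detecting
activated BAT through the warmth of the overlying skin, but its accuracy is
limited by two measurement errors: the operator-dependent delineation of the
region of interest (ROI) — typically variable by 5–15 cm² — and the camera's
temperature readout, with thermal sensitivities of 0.005–0.05 K.  `batirt`
quantifies how these two error sources propagate to the radiated heat power
and which one dominates for a given ROI size and activation temperature
rise.  The practical upshot: for small (neonatal, < 50 cm²) ROIs the
segmentation error dominates, which is exactly the population where IRT-based
BAT studies are most popular.

## The model

The power captured by the camera from an ROI of area *A*, temperature *T*
and emissivity *ε* follows the Stefan–Boltzmann law

```
E = σ ε A T⁴ ,        σ = 5.6 × 10⁻⁸ W m⁻² K⁻⁴
```

With independent errors ΔA and ΔT (one standard deviation each), first-order
propagation gives

```
ΔE² = σ²ε² ( T⁸ ΔA²  +  16 A² T⁶ ΔT² )
      ︸ area term εA ︸   ︸ temperature term εT ︸
```

and the dimensionless **error ratio**

```
ρ = εA / εT = T² ΔA² / (16 ΔT² A²)
```

decides which source dominates: ρ > 1 → ROI-area error, ρ < 1 → temperature
error.  The contributions are equal at the **crossover area**
`A* = T ΔA / (4 ΔT)`: with ΔA = 10 cm² and ΔT = 0.01 K this is 375 cm² at a
1.5 K activation rise and 50 cm² at a 0.2 K rise.

An independent Monte Carlo check perturbs A ~ N(A, σ_A²), T ~ N(T, σ_T²) and
maps the **log conditional-variance ratio**

```
ρ(A,T) = ln( A² Var(T⁴) / (T⁸ Var(A)) )
```

over the physiological lattice A ∈ {1, 20, …, 400} cm², T ∈ {0.1, …, 1.5} K
(positive: temperature error dominates; negative: area error dominates).
Because T⁴ is a polynomial in a Gaussian variable, Var(T⁴) also has an exact
closed form that serves as the deterministic oracle for the sampled grid.

A synthetic-thermogram module closes the loop empirically: it renders 2D
skin-temperature fields with a warm elliptical BAT footprint, camera noise
and calibrated operator segmentation jitter, and verifies that the simulated
variance of the measured power matches the analytic budget.

## Worked example

```
$ batirt budget --area 50 --temp 0.2
{
  ...
  "rho": 1.0,
  "crossover_cm2": 50.0,
  "dominance": "comparable"
}
```

A 50 cm² ROI at a 0.2 K rise sits exactly on the crossover: segmentation and
temperature errors contribute equally (ρ = 1).  Crossover areas and the ρ
coefficient bounds over the physiological temperature range:

```
$ batirt crossover --temps 0.2,1.0,1.5
  "crossovers": [
    {"temp_K": 0.2, "crossover_cm2": 50.0},
    {"temp_K": 1.0, "crossover_cm2": 250.0},
    {"temp_K": 1.5, "crossover_cm2": 375.0}
  ],
  "bound_coefficients": {"low": 25.0, "high": 1406.25}
```

i.e. over 0.2 ≤ T ≤ 1.5 the ratio is bracketed by
`25 (ΔA/A)² ≤ ρ ≤ 1406.25 (ΔA/A)²`.  Other subcommands: `ratio` (one-point
verdict), `grid` (Monte Carlo ρ(A,T) grid as CSV/JSON, optional red/green
PNG), `simulate` (synthetic thermogram + replicate measurement table) and
`validate` (empirical-vs-analytic budget on neonate/crossover/adult
reference scenes; exit code 2 if a tolerance fails).

Library use mirrors the CLI:

```python
from batirt import ErrorModel, crossover_area, MCConfig, grid_scan

errors = ErrorModel(delta_area_cm2=10, delta_temperature_K=0.01)
crossover_area(1.5, errors)        # 375.0 cm^2
grid = grid_scan(MCConfig(n_samples=100_000, seed=0))
grid.to_csv("rho_grid.csv")        # 21 x 15 lattice, sign map + boundary
```

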