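# Methods

## Model and scope

`batirt` analyses the measurement uncertainty of infrared-thermography (IRT)
detection of brown adipose tissue (BAT).  The measurement model is the
Stefan–Boltzmann law, E = σεAT⁴, applied to the skin region of interest
(ROI) overlying a BAT depot: A is the delineated ROI area, T the
temperature entering the fourth-power law, ε the skin emissivity and
σ = 5.6 × 10⁻⁸ W m⁻² K⁻⁴ the Stefan constant.  The two-significant-figure
σ is kept deliberately so that all worked numbers match the analysis this
package operationalizes (CODATA: 5.670 × 10⁻⁸); since every dominance
statistic is a ratio, σ and ε cancel everywhere except in absolute power.

Two error sources are modelled, treated as independent (zero covariance):

* ΔA — operator-dependent ROI delineation, order 5–15 cm², default 10 cm²;
* ΔT — temperature readout error at the camera's thermal-sensitivity scale
  (0.005–0.05 K), default 0.01 K for the analytic budget.

Both magnitudes are interpreted as one standard deviation of a Gaussian;
an optional uniform family with matched sd is provided for sampling paths.
First-order (delta-method) propagation gives
ΔE² = σ²ε²(T⁸ΔA² + 16A²T⁶ΔT²), the error ratio
ρ = T²ΔA²/(16ΔT²A²) and the crossover area A* = TΔA/(4ΔT).

A note on T: the analytic budget is applied with T interpreted as the
activation temperature *rise* (0.1–1.5 K), following the convention of the
source analysis; the formulas themselves are agnostic, and the radiometry
layer accepts absolute temperatures equally.  The two readings are not
reconciled here — the ratio algebra is identical either way because T
enters both components through the same powers up to the explicit T²
factor in ρ.

### The squared-ΔA convention

The published chain for ρ ends in a form linear in ΔA, which is
dimensionally inconsistent with its own starting point
ρ = T⁸ΔA² / (16 · 0.01² · T⁶A²).  This package implements the squared
form, ρ = 625 T² ΔA²/A² at ΔT = 0.01 K, which follows from the first
equality and uniquely reproduces both published crossovers (375 cm² at
T = 1.5 K, 50 cm² at T = 0.2 K with ΔA = 10 cm²).  Correspondingly the
bound coefficients over T ∈ [0.2, 1.5] are 25 and 1406.25 (the upper one
is commonly quoted truncated to 1406).

Dominance classification is a strict binary split at ρ = 1 by default
(`band = 0`), with a configurable symmetric band for a "comparable"
verdict; a relative guard of 10⁻⁹ keeps the exact crossover classified as
comparable under floating-point noise.

## Monte Carlo conditional-variance grid

The independent check perturbs A ~ N(A, σ_A²) and T ~ N(T, σ_T²) and
evaluates ρ(A,T) = ln(A²·Var(T⁴) / (T⁸·Var(A))) on the lattice
A ∈ {1, 20, 40, …, 400} cm² × T ∈ {0.1, …, 1.5} K (21 × 15 cells).
Positive cells mean the temperature-induced variance contribution exceeds
the area-induced one.  (The conventional labels Var(E|A)/Var(E|T) are kept
in the field's notation, but arithmetically the numerator is the
*temperature*-error contribution A²Var(T⁴); the implementation follows the
arithmetic and the sign interpretation, not the label.)

Estimator choices:

* unbiased (n−1) sample variances; Var(A) is sampled rather than replaced
  by σ_A², mirroring the stated simulation (substitution available via
  `use_exact_area_variance` to remove one noise source);
* natural logarithm — the lattice's A-direction cell differences equal
  2·ln(A₂/A₁) (e.g. 2 ln 20 ≈ 5.99 between rows 1 and 20), a σ-independent
  identity that the reference grid satisfies and which fixes the log base;
* per-cell RNG substreams keyed by (seed, row, column), so grids are
  bitwise reproducible and independent of evaluation order;
* a delta-method standard error per cell, Var(ln V̂) ≈ (κ−1)/n summed over
  both variance estimators (κ the kurtosis of the summand), used by the
  test suite for 3-SE consistency checks;
* n = 10⁶ draws per cell for reports and the acceptance script; the test
  suite scans the full lattice at 10⁵ per cell (a few seconds, per-cell SE
  ≈ 0.006), sizes chosen as the package's reporting defaults.

**σ calibration.**  The analytic budget's reference ΔT is 0.01 K, but the
reference grid this scan reproduces is consistent with σ_T = 0.02 K,
σ_A = 10 cm² (e.g. its (400 cm², 1.5 K) cell is 1.514338 against a
linearized ln(1024/225) = 1.5153 at σ_T = 0.02; at σ_T = 0.01 every cell
would shift by −ln 4 ≈ −1.386).  The grid default is therefore
σ_T = 0.02 K — inside the 0.005–0.05 K sensitivity span — while the
analytic module keeps 0.01 K; the discrepancy is deliberate and surfaced
here rather than hidden.  Exact cell-by-cell reproduction of the reference
grid is not claimed: its sample count is unpublished, and at the smallest
T/σ_T its values sit between the linearized and the exact-moment
predictions (e.g. at A = 1 cm², T = 0.1 K: −5.05 linearized, −4.67 exact,
−5.02 printed).  Reproduction is asserted where the regimes agree (high
T/σ_T cells, sign pattern, σ-independent cell differences).

**Exact oracle.**  For X ~ N(μ, σ²),
Var(X⁴) = 16μ⁶σ² + 168μ⁴σ⁴ + 384μ²σ⁶ + 96σ⁸ — an all-positive central
form evaluated directly (the naive E[X⁸] − E[X⁴]² difference cancels
catastrophically at small σ).  The closed form is verified against
numerical quadrature to 10⁻¹⁰ relative; the sampled grid is checked
against ln(A²Var(T⁴)/(T⁸σ_A²)) cell by cell.  The leading deviation from
the linearized limit is +10.5·(σ/μ)² relative, ≈ 0.19% at T/σ = 75.

**Dominance boundary.**  Each temperature column is scanned for its
negative→positive sign change and the zero is linearly interpolated in A;
columns of uniform sign report no boundary.  In the linearized regime the
boundary follows A(T) = (σ_A/4σ_T)·T = 125·T at the default sigmas, i.e.
roughly 15 cm² at T = 0.1 up to 190 cm² at T = 1.5 — consistent with the
usual "area-dominated below ~50 cm², temperature-dominated above
~200 cm²" summary, which the full T-dependent boundary shows to be an
approximation rather than a uniform cutoff.

## Synthetic thermograms

The simulator exists to validate the analytic budget end to end, not to
imitate a specific camera.  A scene is a uniform skin background
(306–307 K) plus a warm elliptical plateau raised by the activation rise,
a cosine edge ramp, i.i.d. per-pixel Gaussian camera noise, and two
modelling choices that require justification:

* **Per-frame offset noise** (`frame_offset_sigma`).  Averaging the
  readout over an ROI of thousands of pixels would suppress i.i.d. noise
  to ~10⁻⁴ K, orders below any camera's accuracy; real sensor error has a
  spatially correlated component (drift, calibration) at the NETD scale.
  A per-frame scalar offset at 0.01–0.02 K realizes the stated ΔT regime.
  Without it the temperature error term would be unmeasurably small and
  the ρ ≈ 1 crossover scenario unrealizable in simulation.
* **Plateau margin** (`plateau_margin`).  The warm footprint extends a few
  cm beyond the nominal ROI before ramping (heat spreads laterally in
  tissue; operators delineate inside the warm patch).  With the margin
  larger than typical jitter excursions, every perturbed mask samples only
  full-rise pixels, so the measured mean temperature is independent of the
  delineation — the independence the analytic model assumes.  With zero
  margin the jitter induces a correlated temperature error and the
  comparison would conflate model error with simulation artefact.

The ROI temperature statistic is the *mean* over the mask (not the
maximum); this is configurable in the sense that `measure_roi` returns the
mean and callers may substitute their own reduction.

**Operator jitter.**  Two modes, both calibrated in closed loop to a target
area-error standard deviation (default 10 cm²):

* `boundary_noise` — the signed distance to the ROI contour is offset by a
  smooth random field (Gaussian-filtered white noise, correlation length
  2 cm, generated on a decimated lattice for speed); the largest connected
  component is kept and holes filled, so masks remain simply connected.
  The field scale is calibrated by two pilot rounds of 400 deterministic
  draws (the area response is nearly linear in the scale); the calibration
  depends only on (mask, jitter parameters), is cached, and is independent
  of the caller's seed.  Across 500 operator realizations the achieved sd
  is within a few percent of target.
* `affine_offset` — a uniform in/out boundary offset plus an integer-pixel
  translation.  The area response to a uniform offset is the quantile
  function of the signed distance, so the offset sd is solved exactly by
  Gauss–Hermite quadrature and bisection (no pilot sampling).

**Empirical budget.**  `empirical_error_budget` draws n replicates
(default 600; the test suite uses 800) of (fresh operator mask, fresh
noisy frame), measures (A, rise) per replicate and computes E = σεA·rise⁴.
Two ablation runs isolate components: the same masks on a noiseless frame
(area component) and the true mask on noisy frames (temperature
component).  The simulated total variance is compared with
`propagate_error` evaluated at the *empirical* (ΔA, ΔT); agreement is
within 15% on the reference scenes, the residual being variance-estimator
noise (rel. SE ≈ √(2/n)) plus the delta-method truncation at
ΔA/A ≈ 0.2–0.3.  Variances that are exactly zero in the ablation logic
(e.g. a noiseless temperature run) are floored at the ulp level of the
power to avoid 10⁻⁵⁷-scale ratios from mean-subtraction rounding.

**Reference scenes.**  Three presets define the validation conditions:

| scene     | ROI (π·a·b)        | rise  | offset σ | regime                    |
|-----------|--------------------|-------|----------|---------------------------|
| neonate   | ~32 cm²            | 0.2 K | 0.01 K   | area-dominated (ρ ≈ 1.9)  |
| crossover | ~48 cm² (meas. ~50)| 0.2 K | 0.01 K   | comparable (ρ ≈ 1)        |
| adult     | ~400 cm²           | 1.5 K | 0.02 K   | temperature-dominated     |

The crossover ellipse is drawn slightly under 50 cm² because the
boundary-noise operator carries a small positive mean area bias (keeping
the largest filled component adds slightly more often than it removes);
the replicate-mean measured area lands at ≈ 50 cm².  The adult scene uses
the 0.02 K offset — the same calibration as the variance-ratio grid, and
the regime in which ROIs above ~200 cm² are robustly
temperature-dominated; at ΔT = 0.01 K the crossover sits at 375 cm² and a
400 cm² scene would leave only ~12% margin to classification noise.

### What the simulator does not model

No lens PSF or optics, no emissivity maps or reflected radiation, no
spatially varying background (vasculature, anatomy), no motion or
perspective distortion, no real IRT file formats, and no human data.
Passing validation therefore shows that the analytic budget is
self-consistent under its own assumptions (independent, roughly Gaussian
errors of the stated magnitudes), not that those magnitudes describe any
particular camera or operator population — ΔA and ΔT remain inputs to be
estimated per protocol.

## Degenerate inputs and numerical conventions

* ΔT = 0 makes ρ unbounded: `error_ratio` returns `inf` by default or
  raises, configurable; `crossover_area` raises `NoCrossoverError`.
* Zero sample variance in a Monte Carlo cell raises
  `DegenerateSampleError` with the cell coordinates attached.
* A jitter magnitude that empties a mask raises `MaskDegenerateError`.
* Areas are cm² at every interface; m² conversion happens only inside
  absolute-power expressions.  The `ErrorBudget` components are stored in
  SI so that ΔE² = σ²ε²(εA + εT) holds exactly; the cm²-based components
  of the printed formulas live in the budget module — the two differ by a
  fixed unit factor that cancels in every ratio.
* Grid CSV output uses the reference layout (A labels down the first
  column, T across the header) at 6 decimals; thermograms are written as
  16-bit TIFF at 0.001 K per digital number with a JSON sidecar; masks as
  8-bit PNG.  Celsius I/O is supported only through explicit conversion
  helpers — internal temperatures are kelvin.

## Known limitations

* The analytic/grid ΔT discrepancy (0.01 vs 0.02 K) is inherited from the
  source analysis and kept visible; users comparing the two paths should
  set the sigmas explicitly.
* The low-T/σ cells of the reference grid are not exactly reproducible
  (unpublished sample count; values between the linearized and
  exact-moment predictions), so assertions there are limited to signs and
  σ-independent identities.
* The boundary-noise calibration targets the area-error *sd*; the shape
  distribution of real operator variability (systematic over-drawing,
  anatomical anchoring) is not modelled.
* The delta-method comparison degrades as ΔA/A grows; beyond ~30%
  relative area error the truncation term is no longer negligible against
  the 15% validation tolerance.
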