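# Methods

This note records the models implemented in `epitherm`, their assumptions,
the numerical choices behind them, and what the synthetic-data generators do
and do not emulate.

## TPS forward model

The transient plane source element is modelled as a uniformly powered disc
of effective radius *a* in thermal contact with a homogeneous medium. The
mean rise is ΔT̄(τ) = P₀ π^(−3/2)(ak)⁻¹ D(τ) with τ = tα/a² and D the
disc shape function (triple integral with an I₀ kernel). Assumptions:

* **Effectively homogeneous medium.** The 2 s diffusion length (~450 μm)
  is an order of magnitude larger than the 50 μm device stack, so device
  layers, encapsulation and tissue are treated as one medium; the
  *effective* radius calibrated on known materials (water, ethylene glycol)
  absorbs the residual layered-geometry and convection effects. For this
  sensor class it comes out near half the lithographic radius.
* **Infinite-medium geometry.** The printed shape integral converges to
  D(∞) = 4/(3√π), i.e. a steady mean rise of 4P₀/(3π²ak) — the uniformly
  powered disc *embedded in* an infinite medium (power fed to both sides),
  half the single-half-space disc value. The steady-limit test asserts
  exactly this constant; on skin the absolute prefactor is irrelevant once
  the effective radius is calibrated.
* **Dimensionless time.** τ = tα/a² enters both the forward model and the
  fit; all scalings (linearity in P₀, k⁻¹ dependence at fixed τ) follow
  from the closed form and are asserted to 1e−12.

**Numerics.** The inner double integral concentrates on the diagonal u = v
with width ~σ; substituting v = u + σs gives a kernel
ive(0, uv/2σ²)·exp(−s²/4) that is order-one and smooth for *every* σ, so
fixed 64-point Gauss–Legendre in each direction converges fast. The
exponentially scaled Bessel function avoids overflow; above z = 1e8 (where
scipy's `ive` degrades) the standard asymptotic series takes over. The
outer integrand f(σ) tends to 1 as σ→0 and to 1/(4σ²) as σ→∞; D is
tabulated once per process as the cumulative Simpson integral of f on a
2001-point geometric grid over [1e−6, 200] and interpolated with a
monotone PCHIP in log τ (below the grid D ≈ τ; above it, the analytic
1/(4τ) tail). Adaptive quadrature of the same integrand remains available
(`method="quad"`) and the test suite checks both paths against two
independent oracles: nested adaptive quadrature in rotated disc
coordinates, and the Hankel-space identity
D(τ) = √π ∫₀^∞ (J₁(μ)/μ)² erf(μτ) dμ. Agreement is at the 1e−5 level,
well inside the 0.1% the fits require.

**Simplified erfc model.** The source typesets the erfc argument
ambiguously; the implementation uses erfc(A₂/(2√(αt))) — the point-source
half-space form with effective distance A₂ — which reproduces both limits
(T→T∞ as t→0⁺, plateau A₁P₀/(2πA₂k) as t→∞). With (A₁, A₂) calibrated
against an exact-model curve the approximation stays within ~5% of peak
over the fitted window. The diffusion-length prefactor Π is kept at 1 by
default (it is "of order unity"; nothing in the data constrains it).

## Inverse fitting

`TPSModel.fit` minimises Σ(ΔT_model − ΔT_meas)² over (k, α) with
scipy's bounded trust-region least squares; tolerances ftol=1e−10,
xtol=1e−8 make results deterministic given the initial point. Defaults:
init (k, α) = (0.3 W/m/K, 0.10 mm²/s) and bounds k ∈ [0.05, 1.5],
α ∈ [0.01, 0.5] mm²/s — the physiological envelope for skin. Constant or
all-zero curves raise a degenerate-input error; optimizer non-convergence
is flagged on the result, not raised. An optional
`exclude_initial_fraction` drops the early transient (default 0: fit all
samples; 0.05 mirrors the first-5% exclusion variant sometimes used because
the earliest samples are most affected by the device's own layers).

The late transient is near-steady and pins k; α only bends the curve's
shape, so its uncertainty is an order of magnitude larger. Diagnostics
expose this directly: the perturb-and-refit scan (fix one parameter at
(1+δ)× best, refit the other) and the SSE error surface on a ±15%, 31×31
grid, whose valley is strongly elongated along α. On the noiseless
surrogate (k=0.4, α=0.10, a=0.254 mm) fixing α +5% shifts k by 1.16%
while fixing k +5% shifts α by 16.4%. Grid ties resolve to smallest k,
then smallest α (row-major argmin), so reporting is deterministic.

Effective-radius calibration minimises the summed SSE over reference
materials with (k, α) held at their known values, using bounded scalar
minimisation on a ∈ (0.02 mm, true radius]; per-material optima spreading
by >20% of their mean trigger a consistency warning.

## Effective-medium unit cells

Square (2D, cylindrical inclusion, max fill π/4 ≈ 78%) or cubic (3D,
spherical inclusion, max fill π/6 ≈ 52.4% — the source rounds this to 50%)
cells of side d = 1 mm. Inclusion membership is by cell-centre test, with
the radius set from the volume fraction (x = πr²/d², x = 4πr³/3d³).

* **Conductivity**: steady conduction with T = 0/1 on two opposite faces,
  insulated elsewhere; regular-grid finite volume with *harmonic* face
  averaging (flux-continuous across the phase interface); k_cell from
  Fourier's law on the computed boundary flux. The linear system is solved
  directly up to 20k unknowns and with Jacobi-preconditioned CG
  (rtol 1e−10) beyond — the matrix is symmetric positive definite.
  Defaults grid_n = 64 (2D) / 32 (3D) keep self-convergence under 1% and
  a full sweep under a second. Results are scale-invariant in d (asserted)
  and always inside the arithmetic/harmonic mixture bounds.
* **Heat capacity**: the adiabatic cell is evaluated by energy bookkeeping,
  ΔT = Q/Σρ_iC_p,iV_i, which is exact at equilibrium (no time stepping);
  the result is the volumetric rule of mixtures up to the discretised
  inclusion volume (<1% at the default grids, identical in 2D and 3D, and
  independent of the injected Q).
* **Diffusivity**: α(x) = k(x)/ρC_p(x) with the *volumetric* mixture of
  ρC_p in the denominator — the same quantity the adiabatic cell returns.
  (Composing ρ(x) and C_p(x) linearly and multiplying differs by up to
  2.4% at x = 0.5 and would blur the monotonicity structure.) With
  rule-of-mixtures k the curve is strictly decreasing; with the unit-cell
  k(x) it develops an interior minimum: dα/dx < 0 below x ≈ 0.5 and > 0
  above, because C_p grows faster than k until the inclusions begin to
  dominate conduction. The constant-density slope approximation
  (ρ̄ = 950 kg/m³) is implemented for the sign analysis it supports; note
  it is *not* quantitatively accurate wherever dα/dx is small (the dropped
  density term is of the same order there), and the tests therefore check
  its exactness in the constant-density limit and its sign structure
  rather than a percentage agreement.

Phase constants: dry skin ρ = 900 kg/m³, C_p = 1500 J/kg/K,
k = 0.2 W/m/K; water 1000, 4200, 0.6. The derivative
d(ρC_p)/dx = (dρ/dx)C_p(x) + (dC_p/dx)ρ(x) has components (1.5e5, 2.43e6)
at x = 0 and (4.2e5, 2.7e6) at x = 1: the specific-heat term dominates at
both ends (by factors ~16 and ~6.4).

## Impedance, DSC, AUC

The EIS element is represented by a single parallel-RC dispersion,
Z = 1/(G + i2πfC) with G = σ/κ and C = εε₀/κ for cell constant κ — an
explicit *surrogate* for the full electrode field problem, adequate for
trends (hydrated |Z| < dehydrated |Z| at every frequency, capacitive phase
in (−90°, 0°)) and descriptor plumbing, not for field maps. The
measurement-depth rule is depth = gap/2, with the gap read as the radial
spacing (OD − ID)/2 of the concentric pair. DSC processing implements
C_p = h/(Bβ) with B calibrated on a reference material; baseline
subtraction and pan-mass normalisation are assumed done upstream. The AUC
descriptor is the trapezoidal integral of (value − baseline) over time —
exact for piecewise-linear profiles and additive over partitions.

## Synthetic data

Generators emulate the study conditions: 7 mW/mm² over a 0.5 mm element
for 2 s (effective radius 0.254 mm), sampled at 100 Hz (200 samples; the
acquisition rate is not documented, and 100 Hz resolves the transient
comfortably); additive i.i.d. Gaussian temperature noise, defaulting to 1%
of a typical peak rise (thermistor-class precision). The hydration sweep
drives the forward model with unit-cell k(x) and volumetric ρC_p(x); the
clinical generator produces the six protocol time points
(−15, 0, 30, 60, 270, 300 min) for four arms (occlusive patch; 0/15/30%
glycerin lotions) with effect profiles shaped to the published
phenomenology: patch effects decay to baseline within ~30 min (patch
duration is a parameter, default 15 min — the source states both 15 and
30 min); glycerin arms plateau and retain about half of their thermal
effect after removal while impedance and the corneometer index largely
return to baseline. All generators are bit-reproducible under fixed seeds
(child seeds are spawned per curve).

What the generators do **not** emulate: location-to-location biological
variability (the dominant error source in real skin data), contact
resistance, sensor-to-sensor geometric variation, drift, glycerin
pharmacodynamics, or multi-layer hydration gradients. Passing round-trip
tests therefore demonstrates correctness of the estimator under the
model's own noise assumptions, not field performance.

## Known limitations

* Single-layer, isotropic medium: no multilayer (device/stratum
  corneum/epidermis) analytical solution; the effective radius is a lumped
  correction.
* No formal confidence intervals on (k, α); the sensitivity scan and error
  surface are the uncertainty diagnostics.
* The lumped impedance model has one dispersion; real skin spectra show
  multiple (Cole–Cole-type) dispersions and electrode polarisation.
* Unit cells assume a centred, isolated inclusion below the geometric fill
  limit; percolating water paths beyond max fill are out of scope.
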