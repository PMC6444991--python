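# epitherm

Thermal and electrical measurement analysis for epidermal hydration sensing.

Skin-mounted "epidermal" sensors measure hydration through intrinsic tissue
properties: a transient plane source (TPS) element — a thin resistive disc —
Joule-heats the epidermis for ~2 s while recording its own temperature rise,
from which thermal conductivity *k* and thermal diffusivity *α* are
recovered; concentric-ring impedance electrodes probe the stratum corneum
electrically. Because the thermal properties of water differ strongly from
those of dry tissue, *k* rises nearly linearly with water content, making
the TPS fit a quantitative hydration readout. This package implements the
full analysis chain for researchers working with such devices: the forward
thermal model, the inverse fit with its identifiability diagnostics,
effective-medium models linking water fraction to bulk properties, the
impedance/DSC/AUC descriptor helpers, and seeded synthetic-data generators
for every modality.

## The model

The spatially averaged temperature rise of a disc of radius *a* dissipating
total power *P*₀ into a medium of conductivity *k* is

```
ΔT̄(τ) = P₀ π^(-3/2) (a k)⁻¹ D(τ),       τ = t α / a²
```

where the dimensionless shape function

```
D(τ) = ∫₀^τ dσ σ⁻² ∫₀¹ u du ∫₀¹ v dv · exp(−(u²+v²)/4σ²) · I₀(uv/2σ²)
```

(I₀ the modified Bessel function of the first kind, order zero) encodes the
disc geometry. Both *k* and *α* shape the transient, so a bounded
least-squares fit of a measured curve recovers both, and their ratio gives
the volumetric heat capacity ρC_p = k/α. The probing depth is the diffusion
length Λ = √(αt) ≈ 450 μm for the 2 s protocol — deep enough that the 50 μm
device stack acts as part of one effective medium, with a calibrated
effective radius (~half the lithographic radius) absorbing the residual
geometry. A simplified erfc model
`T = T∞ + A₁P₀/(2πA₂k) · erfc(A₂/(2√(αt)))` supports high-throughput
clinical fitting.

The hydration link is an effective-medium model: a periodic square/cubic
cell of dry-skin matrix (ρ=900 kg/m³, C_p=1500 J/kg/K, k=0.2 W/m/K) holding
a cylindrical or spherical water inclusion (1000, 4200, 0.6) at volume
fraction *x*. Finite-volume unit-cell solves give k(x) (bracketed by the
arithmetic/harmonic mixture bounds) and ρC_p(x) (exactly the volumetric rule
of mixtures), from which α(x) = k(x)/ρC_p(x) turns out non-monotone with an
interior minimum near x ≈ 0.5.

## Worked example

```python
import numpy as np
from epitherm import ThermalProperties, TPSModel
from epitherm.synthetic import default_sensor, generate_transient, NoiseModel

sensor = default_sensor()                     # 0.5 mm disc, 7 mW/mm², 2 s
skin = ThermalProperties(k=0.4, alpha=0.10)   # porcine-like epidermis
curve = generate_transient(skin, sensor, noise=NoiseModel(sigma=0.05, seed=7))
result = TPSModel(curve, sensor).fit()
print(result.summary())
```

```
TPS transient fit
=================
samples fitted        : 200
converged             : True
k      (W m^-1 K^-1)  : 0.3997
alpha  (mm^2 s^-1)    : 0.0993
rho*Cp (J m^-3 K^-1)  : 4.025e+06
SSE    (K^2)          : 0.3781
RMSE   (K)            : 0.04348
effective radius (mm) : 0.254
power P0 (W)          : 0.005498
```

Despite 50 mK of added noise, *k* comes back within 0.1% and *α* within 1%
of the generating values; ρC_p is their ratio. The identifiability
asymmetry is visible in a perturb-and-refit scan — fixing *k* 5% high and
refitting only *α* drags the diffusivity up by ~16%:

```python
print(result.sensitivity_scan("k", [-0.05, 0.05]).to_string(index=False))
```

```
 perturbation  fixed_k  refit_alpha  fractional_shift      sse  converged
        -0.05 0.379702     0.085148         -0.142457 4.141934       True
         0.05 0.419671     0.115509          0.163316 4.156077       True
```

whereas the mirror-image scan (`result.sensitivity_scan("alpha", ...)`)
moves *k* by only ~1%. `result.error_surface()` materialises the same
structure as an SSE map over a (k, α) grid — a valley strongly elongated
along the α axis.

The same functionality is available from the shell:

```sh
epitherm simulate --kind transient --out fixtures --seed 3 --k 0.4 --alpha 0.1
epitherm fit fixtures/transient.csv
epitherm emm --x-min 0 --x-max 0.5 --n 11 --out emm.csv
```

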