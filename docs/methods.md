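# Methods

## Constitutive model

`afmech` implements the Holzapfel–Gasser–Ogden (HGO) strain-energy function
for the annulus fibrosus, reduced to its incompressible three-constant form:
an isotropic neo-Hookean ground substance reinforced by two exponential,
tension-only collagen fiber families,

```
W = C10 (Ī1 − 3) + K1/(2 K2) Σ_α [exp(K2 Ē_α²) − 1],
Ē_α = κ (Ī1 − 3) + (1 − 3κ)(Ī4(α) − 1),
```

where Ī1 = tr C̄ and Ī4(α) = a₀α · C̄ a₀α are invariants of the distortional
right Cauchy–Green tensor C̄ = J^(−2/3) FᵀF, a₀α are unit reference fiber
directions, and the sum runs over the *active* families only.  With the
`exp(K2 Ē²) − 1` bracket the energy vanishes exactly at the reference state;
this is the standard form of the dispersed-fiber HGO model and the one
implemented here.

A quasi-incompressible variant retains the volumetric term
`(1/D)((J² − 1)/2 − ln J)`; it exists purely to cross-verify the exact
formulation (the consistency check at D = 10⁻⁶ MPa⁻¹ agrees with the
incompressible uniaxial stress at λ = 1.1 to ~2·10⁻⁷ relative).  In the
default, exactly incompressible mode the hydrostatic pressure is a Lagrange
multiplier determined by traction conditions; the energy kernel depends
only on the distortional deformation and is therefore well defined for any
J > 0, which is what makes the finite-difference stress oracle
(σ = J⁻¹ (∂W/∂F) Fᵀ by central differences) straightforward.  The J = 1
constraint is enforced where deformation states are constructed — by the
protocol solvers — not inside the kernel.

### Tension–compression switch

A family contributes only when its dispersion-weighted strain is tensile,
Ē_α > 0.  For aligned fibers (κ = 0, the default and the value used by both
reference parameter sets) this is *identical* to the fiber-extension
criterion Ī4 > 1.  We key the switch on Ē rather than Ī4 because for fully
dispersed fibers (κ = 1/3) the energy must be isotropic — independent of
the now-meaningless nominal direction vectors — and only the Ē-based switch
has that property.  Energy and stress are continuous across the switch
because Ē and ∂W/∂Ē vanish there.

### Coordinates and fiber architecture

x₁ = circumferential, x₂ = radial, x₃ = axial.  The default architecture is
two mirror-symmetric families at ±30° from the circumferential direction in
the (x₁, x₃) lamellar plane: a₀ = (cos 30°, 0, ±sin 30°).  A consequence
worth stating because it is easy to get wrong: under *equibiaxial* in-plane
stretch the two families carry equal Ī4 and the in-plane shear stress
vanishes (mirror symmetry), but σ₁₁ > σ₃₃ — the fiber contribution projects
with cos²30° = 0.75 onto the circumferential axis versus sin²30° = 0.25
onto the axial axis.  The in-plane normal stresses are *not* equal.

## Reference parameter sets

Two literature parameter sets for human annulus fibrosus ship as packaged
JSON fixtures (units MPa; κ = 0; ±30° fibers):

| set | C10 | K1 | K2 |
|---|---|---|---|
| uniaxial-derived | 0.035 | 0.296 | 65 |
| biaxial-derived | 0.85 | 2.8 | 90 |

The uniaxial set was characterized in uniaxial tension, the biaxial set in
planar biaxial tension.  C10 is interchangeable between neo-Hookean and
Mooney–Rivlin matrix descriptions under incompressibility.  The headline
analysis contrasts the two sets at the material point; published
segment-level differences (ranges of motion, intradiscal pressures) come
from finite-element models of a whole spinal segment with geometry this
package deliberately does not model, and are not comparable to the
material-point ratios reported here.  The comparison summary embeds a
`scope` note to prevent that conflation.

## Protocol solvers

All protocols are homogeneous deformations on stretch grids; the default
grid is λ ∈ [1.0, 1.3] with 31 points, which covers the toe and exponential
regimes for K2 of 65–90 without overflowing exp(K2 Ē²) (a guard errors out
above K2 Ē² > 700 rather than returning inf).

* **Uniaxial stress.**  The imposed stretch leaves two transverse stretches
  and the pressure unknown.  The pressure is eliminated analytically from
  one zero-traction condition (p equals the corresponding deviatoric normal
  stress), and incompressibility fixes the second transverse stretch, so a
  single scalar equation — equality of the two transverse deviatoric
  stresses — remains.  It is solved by a secant iteration warm-started from
  the previous grid point, with a bracketing (Brent) fallback; converged
  points satisfy |σ_lateral| < 10⁻⁹ MPa and |λ₁λ₂λ₃ − 1| < 10⁻¹⁴.  The
  continuation tracks the energy-minimizing branch: we verified against a
  brute-force one-dimensional energy minimization that the solved lateral
  stretches minimize total energy at fixed imposed stretch.  With the stiff
  fiber sets the anisotropic lateral contraction is dramatic (axial stretch
  ≈ 0.19 at λ_circ = 1.3 for the biaxial set); that is a property of the
  model at these constants, not a solver artifact.
* **Planar biaxial.**  Both in-plane stretches imposed; λ₂ = 1/(λ₁λ₃) and
  p from σ₂₂ = 0 make every point a closed-form evaluation (no iteration in
  incompressible mode).  Fixing λ₃ to the uniaxial solver's solved axial
  stretch reproduces the uniaxial stress state to < 10⁻⁶ MPa — the two
  solvers cross-check each other.
* **Simple shear** in the fiber plane, F = I + γ e₁⊗e₃: exactly one family
  extends for γ ≠ 0, so the normal-stress pattern is asymmetric under
  γ → −γ while the matrix shear stress 2 C10 γ is odd.

Uniaxial loading along the radial axis is permitted; it shortens both
families (Ī4 = 1/λ < 1) and exercises the matrix-only response.  Nominal
(first Piola–Kirchhoff) stress is the primary reported measure — it is what
a stretch-controlled rig measures — with Cauchy stress co-reported.

## Synthetic data

The generator emulates stretch-controlled uniaxial and planar-biaxial tests:
exact stretch grids, and multiplicative Gaussian noise on each *measured*
stress channel, P ← P·(1 + ε), ε ~ N(0, σ_rel), independent per point, with
σ_rel = 0.02 by default.  Multiplicative rather than additive noise because
the stress spans ~3 orders of magnitude from toe to exponential regime, so
constant relative error is the realistic load-cell contract — and it is the
error structure the relative-residual loss assumes.  The matching Cauchy
component receives the same factor (it derives from the same force
reading).  What the generator does **not** emulate: specimen-to-specimen
variability, degeneration grades, clamping and edge effects, rate
dependence, stretch-measurement error.  Passing recovery tests therefore
show the estimation machinery is correct and well-conditioned under the
assumed error model, not that real-rig data would behave as well.

## Parameter estimation

Nonlinear least squares on the sum of squared relative residuals of nominal
stress (denominator floored at 10⁻⁸ MPa so exact-zero reference points
contribute zero residual).  C10, K1, K2 are optimized in log space — the
two reference sets differ by factors of 9–24, and log-parameterization
makes the box bounds (C10 ∈ [10⁻⁴, 10] MPa, K1 ∈ [10⁻³, 10²] MPa,
K2 ∈ [1, 5·10²]) scale-free; κ, when freed, stays linear since 0 is
admissible.  Multi-start: first start at the (log-)midpoint of the box,
remaining starts log-uniform from a seeded generator; best converged start
wins.  Estimates within 10⁻⁶ (relative) of a bound are flagged.  Data
points are canonically sorted before optimization so the result is bitwise
independent of input ordering.

Fiber-parameter identifiability is checked kinematically before optimizing:
Ī4 depends only on the imposed deformation and the fiber directions, so if
no data point extends any family, K1 and K2 cannot influence the loss and
the fit fails loudly.

Profile likelihood: each free parameter can be profiled by re-optimizing
the others along a grid; the 95% interval uses the standard F-based
threshold SSR ≤ SSR_min (1 + F₀.₉₅(1, n−p)/(n−p)).  On matched point count
and noise, the uniaxial-only protocol leaves the K2 profile dramatically
wider than the combined uniaxial+biaxial protocol (the profile is flat
across a ±15% grid), which is the identifiability face of the study's
theme: uniaxial characterization under-constrains the constants that govern
the in-situ, biaxial stress state.

## Comparison report

`run_comparison` solves identical protocols under both sets and reports
per-point nominal-stress ratios and tangent-stiffness ratios (centered
secant on the imposed grid; verified stable to < 0.5% between 31- and
301-point grids, which is why an analytic second derivative is not needed).
Ratios are set_b/set_a with a = uniaxial-derived, b = biaxial-derived by
convention; denominators below 10⁻¹² MPa yield NaN rather than spurious
ratios.  In the small-strain limit with fibers removed the tangent ratio
reduces to C10,b/C10,a = 24.29 (incompressible Young's modulus 6 C10); with
fibers included the K1 terms contribute to the tangent at first order in
(λ − 1), so the full-model small-strain ratio is *not* the C10 ratio — the
acceptance script reports the measured value.

All report writers are byte-deterministic for fixed inputs (sorted JSON
keys, shortest-round-trip floats, no timestamps); CSV reads use
round-trip float parsing so write/read is exact.

## Problem sizes

Defaults were chosen as the smallest grids that resolve the toe-to-
exponential transition: 31-point grids per curve, 100 random states for the
derivative oracle, 20 replicates for the bias check, 13-point profiles.
The full pipeline (synthesize → fit → compare) completes in well under a
minute on one CPU.

## Known limitations

* Homogeneous material-point mechanics only: no finite-element
  discretization, no specimen geometry, no segment-level kinematics.
* No viscoelasticity, poroelasticity, osmotic swelling, or damage; the
  two-family continuum stands in for the 15–25-lamella laminate.
* The exponential stress growth at these K2 values makes stresses near
  λ = 1.3 physically implausible (10³–10⁸ MPa); the range is retained
  because it is the conventional characterization window, but conclusions
  should be read from the moderate-stretch region.
* The uniaxial-derived constants are assumed to have been measured along
  the circumferential axis; the load axis is configurable where that
  assumption matters.
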