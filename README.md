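# afmech

Anisotropic hyperelastic modelling of the annulus fibrosus — the collagen-
reinforced outer ring of the intervertebral disc — built around the
Holzapfel–Gasser–Ogden (HGO) constitutive model, for biomechanics
researchers who need a testable material-point counterpart to full
finite-element disc models.

The annulus is modelled as an incompressible neo-Hookean ground substance
with two exponential, tension-only collagen fiber families at ±30° from the
circumferential direction:

```
W = C10 (Ī1 − 3) + K1/(2 K2) Σ_α [exp(K2 Ē_α²) − 1]
Ē_α = κ (Ī1 − 3) + (1 − 3κ)(Ī4(α) − 1)
```

with Ī1, Ī4(α) the distortional invariants of FᵀF, κ the fiber dispersion
(0 = aligned, the default), and a family contributing only when extended
(Ē_α > 0).  Units are MPa throughout.

The scientific motivation: published HGO constants for human annulus differ
grossly depending on whether they were fitted to uniaxial tension tests
(C10 = 0.035 MPa, K1 = 0.296 MPa, K2 = 65) or planar biaxial tests
(C10 = 0.85 MPa, K1 = 2.8 MPa, K2 = 90) — yet the tissue in situ is loaded
biaxially.  `afmech` quantifies the mechanical consequence of that choice at
the material point, and shows *why* uniaxial data under-constrain the
constants (profile-likelihood identifiability).

## What's in the box

* `afmech.hgo` / `afmech.kinematics` — strain energy, Cauchy and nominal
  stress, invariants, fiber activation, exact-incompressible and
  penalty formulations.
* `afmech.protocols` — homogeneous boundary-value solvers: uniaxial stress
  (any tissue axis), equibiaxial and general planar biaxial stretch,
  simple shear in the fiber plane; CSV serialization.
* `afmech.synthetic` — stretch-controlled test emulation with seeded
  multiplicative Gaussian noise; packaged fixture generation.
* `afmech.fitting` — multi-start nonlinear least squares for (C10, K1, K2)
  [+ κ], bound/identifiability diagnostics, profile likelihood.
* `afmech.compare` — the headline analysis: identical protocols under both
  parameter sets, stress and tangent-stiffness ratios, deterministic
  CSV/JSON reports.
* `afmech` CLI — `simulate`, `synth`, `fit`, `compare` subcommands.

## Worked example

```python
import numpy as np
import afmech as af

uni, fibers = af.uniaxial_reference()   # uniaxial-derived constants
bia, _ = af.biaxial_reference()         # biaxial-derived constants

spec = af.ProtocolSpec(kind="uniaxial",
                       stretches=list(np.linspace(1.0, 1.15, 4)))
report = af.run_comparison(uni, bia, fibers, [spec])
comp = report.comparisons[0]
for lam, pa, pb, r in zip(comp.abscissa, comp.stress_a,
                          comp.stress_b, comp.stress_ratio):
    print(f"lambda={lam:.2f}  P_uniaxial={pa:8.4f}  "
          f"P_biaxial={pb:8.4f}  ratio={r:6.2f}")
```

prints

```
lambda=1.00  P_uniaxial=  0.0000  P_biaxial=  0.0000  ratio=   nan
lambda=1.05  P_uniaxial=  0.0496  P_biaxial=  0.7564  ratio= 15.25
lambda=1.10  P_uniaxial=  0.1429  P_biaxial=  2.4527  ratio= 17.16
lambda=1.15  P_uniaxial=  0.3726  P_biaxial=  7.2723  ratio= 19.52
```

Read: under circumferential uniaxial stretch the biaxial-derived constants
predict a 15–20× higher nominal stress than the uniaxial-derived constants
over the physiological toe region — the material-point face of the finding
that whole-segment models built on uniaxial constants are far too
compliant.  (The reference point divides 0 by 0, hence the NaN; ratios are
defined wherever the denominator stress exceeds 10⁻¹² MPa.)

The same contrast from the shell:

```sh
afmech compare --out report/     # comparison_points.csv + comparison_summary.json
afmech synth --params uniaxial --seed 1 --out data/
afmech fit --data data/synth_manifest.json --seed 1 --out fit.json
```

See `docs/methods.md` for the model's assumptions, the solvers, the noise
model and its limits, and the design decisions.

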