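"""HGO strain energy and stress evaluation for homogeneous deformations.

Energy density (MPa):

    W = C10 (I1bar - 3)
        [+ (1/D) ((J^2 - 1)/2 - ln J)        in penalty mode]
        + K1/(2 K2) * sum_active [exp(K2 * Ebar_a^2) - 1]

A fiber family is *active* (contributes energy and stress) only when its
dispersion-weighted strain is tensile, Ebar_a > 0: collagen fibers buckle
rather than support compression.  For aligned fibers (kappa = 0, the
default architecture) this is exactly the I4bar_a > 1 extension criterion;
for fully dispersed fibers (kappa = 1/3) it keeps the energy independent
of the nominal direction vectors, as an isotropic term must be.  Both the
energy and the stress are continuous across activation because Ebar_a and
dW/dEbar_a vanish there.

In the exactly incompressible mode (``d_penalty is None``) the hydrostatic
pressure is a Lagrange multiplier fixed by traction boundary conditions,
so :func:`cauchy_stress` takes it from the caller; the protocol solvers in
:mod:`afmech.protocols` determine it.  The energy kernel itself depends
only on the distortional part of F, so it is well defined (and constant
along volumetric paths) for any J > 0 — the J = 1 constraint is enforced
where states are constructed, not here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigurationError, OverflowGuardError
from .kinematics import DeformationState, InvariantSet
from .materials import FiberArchitecture, MaterialParameters

#: exp() argument above which the fiber term would overflow float64.
_EXP_GUARD = 700.0


@dataclass(frozen=True)
class StressResult:
    """Cauchy and nominal (first Piola-Kirchhoff) stress, MPa.

    ``pressure`` is the Lagrange-multiplier hydrostatic term (sign
    convention sigma = sigma_dev - p I); ``None`` in penalty mode where
    the volumetric stress follows from the energy instead.
    """

    cauchy: np.ndarray
    nominal: np.ndarray
    pressure: Optional[float]


def fiber_activation(invariants: InvariantSet) -> np.ndarray:
    """Boolean per family: active iff Ebar > 0 (strict).

    Equivalent to the fiber-extension criterion I4bar > 1 when kappa = 0.
    """
    return invariants.e_alpha > 0.0


def _fiber_exponentials(params: MaterialParameters, inv: InvariantSet):
    """Per-family (active mask, exp(K2 Ebar^2)) with overflow guard."""
    active = fiber_activation(inv)
    arg = params.k2 * inv.e_alpha**2
    if np.any(arg[active] > _EXP_GUARD):
        raise OverflowGuardError(
            f"K2*Ebar^2 = {arg.max():.3g} exceeds the overflow guard {_EXP_GUARD}"
        )
    return active, np.exp(np.where(active, arg, 0.0))


def strain_energy(state: DeformationState, params: MaterialParameters,
                  fibers: FiberArchitecture) -> float:
    """Strain-energy density W, MPa.

    Zero exactly at (and only at, for positive moduli) rigid rotations.
    """
    inv = state.invariants
    w = params.c10 * (inv.i1bar - 3.0)
    if not params.incompressible:
        j = state.j
        w += (1.0 / params.d_penalty) * ((j * j - 1.0) / 2.0 - np.log(j))
    if params.k1 > 0.0:
        active, expfac = _fiber_exponentials(params, inv)
        w += params.k1 / (2.0 * params.k2) * float(np.sum(expfac[active] - 1.0))
    return float(w)


def cauchy_stress(state: DeformationState, params: MaterialParameters,
                  fibers: FiberArchitecture,
                  pressure: Optional[float] = None) -> StressResult:
    """Cauchy and nominal stress of a deformation state.

    Parameters
    ----------
    pressure : float, required in incompressible mode
        The hydrostatic Lagrange multiplier p in sigma = sigma_dev - p I.
        Must be absent (None) in penalty mode, where the volumetric stress
        is (1/D)(J - 1/J) I from the energy.

    The deviatoric part is the standard push-forward of the isochoric
    energy:  sigma_iso = (2/J) dev[ psi1 Bbar + sum_a psi4_a mbar_a (x) mbar_a ]
    with psi1 = dW/dI1bar, psi4_a = dW/dI4bar_a and mbar_a = Fbar a0_a.
    """
    f = state.f
    j = state.j
    inv = state.invariants

    if params.incompressible:
        if pressure is None:
            raise ConfigurationError(
                "incompressible mode: the caller must supply the pressure"
            )
    elif pressure is not None:
        raise ConfigurationError("penalty mode derives its own volumetric stress; "
                                 "do not pass a pressure")

    fbar = j ** (-1.0 / 3.0) * f
    bbar = fbar @ fbar.T

    psi1 = params.c10
    sig = np.zeros((3, 3))
    if params.k1 > 0.0:
        active, expfac = _fiber_exponentials(params, inv)
        dw_de = params.k1 * inv.e_alpha * expfac  # dW/dEbar_a, zero where inactive
        dw_de = np.where(active, dw_de, 0.0)
        psi1 += params.kappa * float(np.sum(dw_de))
        psi4 = (1.0 - 3.0 * params.kappa) * dw_de
        mbar = (fbar @ fibers.directions.T).T  # (N, 3)
        sig += np.einsum("n,ni,nj->ij", psi4, mbar, mbar)
    sig += psi1 * bbar
    sig = (2.0 / j) * (sig - np.trace(sig) / 3.0 * np.eye(3))

    if params.incompressible:
        sig = sig - pressure * np.eye(3)
        p_out: Optional[float] = float(pressure)
    else:
        dvol = (1.0 / params.d_penalty) * (j - 1.0 / j)  # dW_vol/dJ
        sig = sig + dvol * np.eye(3)
        p_out = None

    sig = 0.5 * (sig + sig.T)  # symmetrize away rounding noise
    nominal = j * sig @ np.linalg.inv(f).T
    return StressResult(cauchy=sig, nominal=nominal, pressure=p_out)


def deviatoric_cauchy(state: DeformationState, params: MaterialParameters,
                      fibers: FiberArchitecture) -> np.ndarray:
    """Pressure-independent deviatoric Cauchy stress (incompressible mode).

    Convenience for the protocol solvers, which eliminate the pressure
    analytically from a zero-traction condition.
    """
    if not params.incompressible:
        raise ConfigurationError("deviatoric_cauchy applies to incompressible mode")
    return cauchy_stress(state, params, fibers, pressure=0.0).cauchy
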