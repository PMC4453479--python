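"""Finite-deformation kinematics: deformation gradients and invariants.

The constitutive model is formulated on the distortional (isochoric) part
of the deformation: Fbar = J^(-1/3) F, Cbar = Fbar^T Fbar.  The invariants
carried by :class:`InvariantSet` are

* ``i1bar``  = tr(Cbar), first deviatoric invariant,
* ``i4bar[a]`` = a0_a . Cbar a0_a, squared isochoric fiber stretch of
  family ``a``,
* ``e_alpha[a]`` = kappa (i1bar - 3) + (1 - 3 kappa)(i4bar[a] - 1), the
  dispersion-weighted fiber strain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidDeformationError
from .materials import FiberArchitecture


@dataclass(frozen=True)
class InvariantSet:
    """Isochoric invariants of a deformation state for a fiber architecture."""

    i1bar: float
    i4bar: np.ndarray  # (N,) per fiber family
    e_alpha: np.ndarray  # (N,) per fiber family


def compute_invariants(f: np.ndarray, fibers: FiberArchitecture,
                       kappa: float) -> InvariantSet:
    """Isochoric invariants I1bar, I4bar_a and fiber strains Ebar_a of ``f``.

    Raises
    ------
    InvalidDeformationError
        If det(f) <= 0.
    """
    f = np.asarray(f, dtype=float)
    j = np.linalg.det(f)
    if j <= 0.0:
        raise InvalidDeformationError(f"det(F) = {j:g} must be positive")
    fbar = j ** (-1.0 / 3.0) * f
    cbar = fbar.T @ fbar
    i1bar = float(np.trace(cbar))
    a0 = fibers.directions
    i4bar = np.einsum("ni,ij,nj->n", a0, cbar, a0)
    e_alpha = kappa * (i1bar - 3.0) + (1.0 - 3.0 * kappa) * (i4bar - 1.0)
    return InvariantSet(i1bar=i1bar, i4bar=i4bar, e_alpha=e_alpha)


@dataclass(frozen=True)
class DeformationState:
    """A homogeneous deformation: gradient ``f``, volume ratio ``j`` and
    the invariant set for a given fiber architecture and dispersion."""

    f: np.ndarray
    j: float
    invariants: InvariantSet

    @classmethod
    def create(cls, f: np.ndarray, fibers: FiberArchitecture,
               kappa: float = 0.0) -> "DeformationState":
        f = np.asarray(f, dtype=float)
        inv = compute_invariants(f, fibers, kappa)
        return cls(f=f, j=float(np.linalg.det(f)), invariants=inv)


# ---------------------------------------------------------------------------
# Deformation-gradient builders for the homogeneous protocols
# ---------------------------------------------------------------------------

def principal_f(l1: float, l2: float, l3: float) -> np.ndarray:
    """Diagonal gradient diag(l1, l2, l3) in the (circ, radial, axial) frame."""
    return np.diag([float(l1), float(l2), float(l3)])


def simple_shear_f(gamma: float) -> np.ndarray:
    """Simple shear of amount gamma in the fiber (circumferential-axial)
    plane: F = I + gamma e1 (x) e3.  Isochoric for any gamma."""
    f = np.eye(3)
    f[0, 2] = float(gamma)
    return f


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform random rotation matrix via QR of a Gaussian matrix."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_isochoric_f(rng: np.random.Generator, scale: float = 0.15) -> np.ndarray:
    """A random deformation gradient normalized to det = 1 exactly.

    ``scale`` controls the distance from the identity; the default keeps
    stretches in a physiologically plausible range.
    """
    f = np.eye(3) + scale * rng.standard_normal((3, 3))
    d = np.linalg.det(f)
    if d <= 0.05:  # rare with scale ~ 0.15; resample
        return random_isochoric_f(rng, scale)
    return f / d ** (1.0 / 3.0)
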