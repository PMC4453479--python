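"""Material parameters and fiber architecture for the HGO annulus model.

The annulus fibrosus is modelled as an incompressible neo-Hookean ground
substance reinforced by two collagen fiber families lying in the
circumferential-axial plane at +/-30 degrees from the circumferential
direction.  The strain-energy density is

    W = C10 (I1bar - 3) + K1/(2 K2) * sum_a [exp(K2 * Ebar_a^2) - 1]

with the dispersion-weighted fiber strain
Ebar_a = kappa (I1bar - 3) + (1 - 3 kappa)(I4bar_a - 1), and fiber families
contributing only in extension (I4bar_a > 1).  Units are MPa throughout;
stretches are dimensionless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigurationError

#: Coordinate convention used everywhere in the package.
#: x1 = circumferential, x2 = radial, x3 = axial.
AXIS_NAMES = ("circumferential", "radial", "axial")
AXIS_INDEX = {name: i for i, name in enumerate(AXIS_NAMES)}


class MaterialParameters(BaseModel):
    """Constitutive constants of the reduced (three-constant) HGO model.

    Parameters
    ----------
    c10 : float
        Neo-Hookean matrix stiffness, MPa.  Under incompressibility the
        same constant appears in the Mooney-Rivlin form, so values fitted
        with either matrix model are interchangeable.
    k1 : float
        Fiber stiffness-like parameter, MPa.  ``k1 = 0`` removes the fiber
        contribution entirely (pure neo-Hookean matrix).
    k2 : float
        Dimensionless fiber nonlinearity exponent.
    kappa : float
        Fiber dispersion in [0, 1/3]; 0 = perfectly aligned families,
        1/3 = isotropically dispersed.
    d_penalty : float or None
        Volumetric compliance D, MPa^-1.  ``None`` selects the exactly
        incompressible formulation (D -> infinity); a positive value
        selects the quasi-incompressible penalty formulation, retained for
        cross-verification only.
    label : str
        Free-text provenance tag (e.g. ``"uniaxial"`` or ``"biaxial"``).
    """

    model_config = ConfigDict(frozen=True)

    c10: float = Field(gt=0.0)
    k1: float = Field(ge=0.0)
    k2: float = Field(gt=0.0)
    kappa: float = Field(default=0.0, ge=0.0, le=1.0 / 3.0 + 1e-15)
    d_penalty: Optional[float] = None
    label: str = ""

    @model_validator(mode="after")
    def _check_penalty(self) -> "MaterialParameters":
        if self.d_penalty is not None and self.d_penalty <= 0.0:
            raise ValueError("d_penalty must be positive when present")
        return self

    @property
    def incompressible(self) -> bool:
        """True when the exact kinematic constraint J = 1 is in force."""
        return self.d_penalty is None


@dataclass(frozen=True)
class FiberArchitecture:
    """Reference fiber directions of the lamellar collagen network.

    ``directions`` is an (N, 3) array of unit vectors in the reference
    configuration.  The default architecture is the two-family laminate
    with directions (cos a, 0, +/- sin a), a = 30 degrees, i.e. fibers in
    the circumferential-axial (x1, x3) plane tilted +/-30 degrees from
    circumferential.
    """

    directions: np.ndarray
    angle_deg: Optional[float] = None

    def __post_init__(self):
        dirs = np.atleast_2d(np.asarray(self.directions, dtype=float))
        if dirs.ndim != 2 or dirs.shape[1] != 3 or dirs.shape[0] < 1:
            raise ConfigurationError("directions must be an (N, 3) array with N >= 1")
        norms = np.linalg.norm(dirs, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-12):
            raise ConfigurationError("fiber directions must be unit vectors (tol 1e-12)")
        object.__setattr__(self, "directions", dirs)

    @property
    def n_families(self) -> int:
        return self.directions.shape[0]

    @classmethod
    def symmetric(cls, angle_deg: float = 30.0) -> "FiberArchitecture":
        """Two mirror-symmetric families at +/-angle from circumferential."""
        a = np.deg2rad(angle_deg)
        dirs = np.array(
            [[np.cos(a), 0.0, np.sin(a)], [np.cos(a), 0.0, -np.sin(a)]]
        )
        return cls(directions=dirs, angle_deg=angle_deg)

    def rotated(self, q: np.ndarray) -> "FiberArchitecture":
        """Architecture with every direction rotated by the 3x3 rotation ``q``."""
        return FiberArchitecture(directions=(np.asarray(q) @ self.directions.T).T,
                                 angle_deg=None)


class MaterialConfig(BaseModel):
    """On-disk JSON schema for a material parameter set.

    Keys: ``label``, ``c10_mpa``, ``k1_mpa``, ``k2``, ``kappa``,
    ``d_penalty_per_mpa`` (optional), ``fiber_angle_deg``.
    """

    label: str = ""
    c10_mpa: float
    k1_mpa: float
    k2: float
    kappa: float = 0.0
    d_penalty_per_mpa: Optional[float] = None
    fiber_angle_deg: float = 30.0

    def to_params(self) -> MaterialParameters:
        return MaterialParameters(
            c10=self.c10_mpa,
            k1=self.k1_mpa,
            k2=self.k2,
            kappa=self.kappa,
            d_penalty=self.d_penalty_per_mpa,
            label=self.label,
        )

    def to_fibers(self) -> FiberArchitecture:
        return FiberArchitecture.symmetric(self.fiber_angle_deg)

    @classmethod
    def from_params(cls, params: MaterialParameters,
                    fiber_angle_deg: float = 30.0) -> "MaterialConfig":
        return cls(
            label=params.label,
            c10_mpa=params.c10,
            k1_mpa=params.k1,
            k2=params.k2,
            kappa=params.kappa,
            d_penalty_per_mpa=params.d_penalty,
            fiber_angle_deg=fiber_angle_deg,
        )


def load_material(path: str | Path) -> tuple[MaterialParameters, FiberArchitecture]:
    """Read a material JSON file; returns (parameters, fiber architecture)."""
    cfg = MaterialConfig.model_validate_json(Path(path).read_text())
    return cfg.to_params(), cfg.to_fibers()


def save_material(path: str | Path, params: MaterialParameters,
                  fiber_angle_deg: float = 30.0) -> None:
    cfg = MaterialConfig.from_params(params, fiber_angle_deg)
    payload = cfg.model_dump(exclude_none=True)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _packaged(name: str) -> tuple[MaterialParameters, FiberArchitecture]:
    from importlib import resources

    text = resources.files("afmech").joinpath(f"data/{name}").read_text()
    cfg = MaterialConfig.model_validate_json(text)
    return cfg.to_params(), cfg.to_fibers()


def uniaxial_reference() -> tuple[MaterialParameters, FiberArchitecture]:
    """Literature parameter set fitted to uniaxial tension tests of human
    annulus fibrosus (C10 = 0.035 MPa, K1 = 0.296 MPa, K2 = 65)."""
    return _packaged("uniaxial.json")


def biaxial_reference() -> tuple[MaterialParameters, FiberArchitecture]:
    """Literature parameter set fitted to planar biaxial tension tests of
    human annulus fibrosus (C10 = 0.85 MPa, K1 = 2.8 MPa, K2 = 90)."""
    return _packaged("biaxial.json")
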