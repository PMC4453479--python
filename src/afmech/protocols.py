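"""Homogeneous-deformation boundary-value problems.

Each solver imposes a stretch (or shear) history on a material point and
resolves the remaining kinematic unknowns and the hydrostatic pressure
from zero-traction conditions, producing a :class:`StressStretchCurve`.

* uniaxial stress: stretch imposed along one tissue axis, both lateral
  Cauchy stresses driven to zero; with an anisotropic fiber architecture
  the two lateral contractions differ, so one transverse stretch is a
  root-finding unknown (the other follows from incompressibility and the
  pressure is eliminated analytically).
* planar biaxial stretch: circumferential and axial stretches imposed,
  radial stretch fixed by incompressibility, pressure fixed by zero
  radial stress — a closed-form evaluation, no iteration.
* simple shear in the fiber plane: exercises asymmetric fiber engagement
  (one family extends, the other shortens).

Stresses are reported as nominal (first Piola-Kirchhoff, force per
reference area — what a test rig measures) and Cauchy, both in MPa.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import optimize

from .errors import ConfigurationError, SolverError
from .hgo import cauchy_stress, deviatoric_cauchy
from .kinematics import DeformationState, principal_f, simple_shear_f
from .materials import AXIS_INDEX, FiberArchitecture, MaterialParameters

#: default stretch grid: toe through exponential regime, 31 points
DEFAULT_STRETCH_MAX = 1.3
DEFAULT_N_POINTS = 31

#: stress-residual tolerance for the traction conditions, MPa
STRESS_TOL = 1e-10


def default_stretch_grid(n_points: int = DEFAULT_N_POINTS,
                         stretch_max: float = DEFAULT_STRETCH_MAX) -> list[float]:
    return list(np.linspace(1.0, stretch_max, n_points))


def default_shear_grid(n_points: int = DEFAULT_N_POINTS,
                       gamma_max: float = 0.3) -> list[float]:
    return list(np.linspace(0.0, gamma_max, n_points))


class ProtocolSpec(BaseModel):
    """Specification of a homogeneous test protocol.

    ``stretches`` is the primary (circumferential for biaxial) stretch
    grid; ``axial_stretches`` is the axial grid for ``planar_biaxial``
    (a scalar is broadcast, e.g. a constrained axis held at 1.0);
    ``gammas`` is the shear-amount grid for ``simple_shear``.
    """

    model_config = ConfigDict(frozen=True)

    kind: Literal["uniaxial", "equibiaxial", "planar_biaxial", "simple_shear"]
    load_axis: Literal["circumferential", "radial", "axial"] = "circumferential"
    stretches: Optional[list[float]] = None
    axial_stretches: Optional[list[float] | float] = None
    gammas: Optional[list[float]] = None
    allow_compression: bool = False

    @model_validator(mode="after")
    def _validate(self) -> "ProtocolSpec":
        if self.kind == "simple_shear":
            return self
        grid = self.stretch_grid()
        if np.any(grid <= 0.0):
            raise ValueError("stretches must be positive")
        if len(grid) > 1 and np.any(np.diff(grid) <= 0.0):
            raise ValueError("stretch grid must be strictly increasing")
        if self.kind == "uniaxial" and not self.allow_compression and grid[0] < 1.0:
            raise ValueError("uniaxial stretches must be >= 1 unless "
                             "allow_compression is set")
        ax = self.axial_grid()
        if ax is not None:
            if np.any(ax <= 0.0):
                raise ValueError("axial stretches must be positive")
            if len(ax) != len(grid):
                raise ValueError("axial stretch grid length must match stretches")
        return self

    def stretch_grid(self) -> np.ndarray:
        if self.stretches is None:
            return np.asarray(default_stretch_grid())
        return np.asarray(self.stretches, dtype=float)

    def axial_grid(self) -> Optional[np.ndarray]:
        if self.kind == "equibiaxial":
            return self.stretch_grid()
        if self.kind != "planar_biaxial":
            return None
        ax = self.axial_stretches
        if ax is None:
            return self.stretch_grid()
        if np.isscalar(ax):
            return np.full(len(self.stretch_grid()), float(ax))
        return np.asarray(ax, dtype=float)

    def gamma_grid(self) -> np.ndarray:
        if self.gammas is None:
            return np.asarray(default_shear_grid())
        return np.asarray(self.gammas, dtype=float)


@dataclass
class StressStretchCurve:
    """Per-point stretches and stresses of one protocol solve.

    Index 1 = circumferential, 2 = radial, 3 = axial.  ``pressure`` is the
    solved Lagrange multiplier (incompressible mode).  Shear curves carry
    the shear amount ``gamma`` and the 13 stress components in addition.
    """

    protocol: ProtocolSpec
    params_label: str
    lambda_1: np.ndarray
    lambda_2: np.ndarray
    lambda_3: np.ndarray
    p_11: np.ndarray
    p_22: np.ndarray
    p_33: np.ndarray
    sigma_11: np.ndarray
    sigma_22: np.ndarray
    sigma_33: np.ndarray
    pressure: np.ndarray
    gamma: Optional[np.ndarray] = None
    p_13: Optional[np.ndarray] = None
    sigma_13: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.lambda_1)

    @property
    def loading_nominal(self) -> np.ndarray:
        """Nominal stress along the protocol's primary measure."""
        if self.protocol.kind == "uniaxial":
            return {"circumferential": self.p_11, "radial": self.p_22,
                    "axial": self.p_33}[self.protocol.load_axis]
        if self.protocol.kind == "simple_shear":
            return self.p_13
        return self.p_11  # biaxial: circumferential channel

    @property
    def loading_cauchy(self) -> np.ndarray:
        if self.protocol.kind == "uniaxial":
            return {"circumferential": self.sigma_11, "radial": self.sigma_22,
                    "axial": self.sigma_33}[self.protocol.load_axis]
        if self.protocol.kind == "simple_shear":
            return self.sigma_13
        return self.sigma_11

    @property
    def abscissa(self) -> np.ndarray:
        """The imposed control variable (stretch, or gamma for shear)."""
        if self.protocol.kind == "simple_shear":
            return self.gamma
        if self.protocol.kind == "uniaxial":
            return {"circumferential": self.lambda_1, "radial": self.lambda_2,
                    "axial": self.lambda_3}[self.protocol.load_axis]
        return self.lambda_1

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "protocol": np.full(len(self), self.protocol.kind),
            "load_axis": np.full(len(self), self.protocol.load_axis),
            "params_label": np.full(len(self), self.params_label),
            "lambda_1": self.lambda_1,
            "lambda_2": self.lambda_2,
            "lambda_3": self.lambda_3,
            "P_11_MPa": self.p_11,
            "P_33_MPa": self.p_33,
            "sigma_11_MPa": self.sigma_11,
            "sigma_33_MPa": self.sigma_33,
            "P_22_MPa": self.p_22,
            "sigma_22_MPa": self.sigma_22,
            "pressure_MPa": self.pressure,
        }
        if self.gamma is not None:
            cols["gamma"] = self.gamma
            cols["P_13_MPa"] = self.p_13
            cols["sigma_13_MPa"] = self.sigma_13
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        # pandas' default float formatting is the shortest exact repr, so a
        # read-back reproduces every value bit for bit (RFC-4180 dialect).
        self.to_frame().to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StressStretchCurve":
        kind = str(df["protocol"].iloc[0])
        load_axis = str(df.get("load_axis", pd.Series(["circumferential"])).iloc[0])
        spec_kwargs: dict = {"kind": kind, "load_axis": load_axis}
        if kind == "simple_shear":
            spec_kwargs["gammas"] = list(df["gamma"].to_numpy(float))
        else:
            grid_col = {"circumferential": "lambda_1", "radial": "lambda_2",
                        "axial": "lambda_3"}[load_axis] if kind == "uniaxial" \
                else "lambda_1"
            spec_kwargs["stretches"] = list(df[grid_col].to_numpy(float))
            if kind == "planar_biaxial":
                spec_kwargs["axial_stretches"] = list(df["lambda_3"].to_numpy(float))
        protocol = ProtocolSpec(**spec_kwargs)
        kw = {}
        if "gamma" in df.columns:
            kw = {"gamma": df["gamma"].to_numpy(float),
                  "p_13": df["P_13_MPa"].to_numpy(float),
                  "sigma_13": df["sigma_13_MPa"].to_numpy(float)}
        return cls(
            protocol=protocol,
            params_label=str(df["params_label"].iloc[0]),
            lambda_1=df["lambda_1"].to_numpy(float),
            lambda_2=df["lambda_2"].to_numpy(float),
            lambda_3=df["lambda_3"].to_numpy(float),
            p_11=df["P_11_MPa"].to_numpy(float),
            p_22=df["P_22_MPa"].to_numpy(float),
            p_33=df["P_33_MPa"].to_numpy(float),
            sigma_11=df["sigma_11_MPa"].to_numpy(float),
            sigma_22=df["sigma_22_MPa"].to_numpy(float),
            sigma_33=df["sigma_33_MPa"].to_numpy(float),
            pressure=df["pressure_MPa"].to_numpy(float),
            **kw,
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "StressStretchCurve":
        # round_trip parsing: the default C parser can be off by one ulp,
        # which would break the exact write/read contract
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------

def _diag_f(values: dict[int, float]) -> np.ndarray:
    d = np.ones(3)
    for idx, v in values.items():
        d[idx] = v
    return np.diag(d)


def _assemble(protocol: ProtocolSpec, params: MaterialParameters, rows: list[dict],
              shear: bool = False) -> StressStretchCurve:
    arr = {k: np.array([r[k] for r in rows]) for k in rows[0]}
    kw = {}
    if shear:
        kw = {"gamma": arr["gamma"], "p_13": arr["p_13"], "sigma_13": arr["sigma_13"]}
    return StressStretchCurve(
        protocol=protocol, params_label=params.label,
        lambda_1=arr["l1"], lambda_2=arr["l2"], lambda_3=arr["l3"],
        p_11=arr["p11"], p_22=arr["p22"], p_33=arr["p33"],
        sigma_11=arr["s11"], sigma_22=arr["s22"], sigma_33=arr["s33"],
        pressure=arr["pressure"], **kw,
    )


def _row_from_stress(f: np.ndarray, cauchy: np.ndarray, nominal: np.ndarray,
                     pressure: float) -> dict:
    return {
        "l1": f[0, 0], "l2": f[1, 1], "l3": f[2, 2],
        "p11": nominal[0, 0], "p22": nominal[1, 1], "p33": nominal[2, 2],
        "s11": cauchy[0, 0], "s22": cauchy[1, 1], "s33": cauchy[2, 2],
        "pressure": pressure,
    }


def solve_uniaxial(params: MaterialParameters, fibers: FiberArchitecture,
                   spec: ProtocolSpec) -> StressStretchCurve:
    """Uniaxial stress along ``spec.load_axis``.

    For each imposed stretch the transverse stretches and pressure satisfy
    incompressibility and zero lateral Cauchy stress (|sigma| < 1e-9 MPa).
    Solutions are continued along the grid (warm starts), which keeps the
    scalar root solve in the basin of the physical branch.
    """
    if spec.kind != "uniaxial":
        raise ConfigurationError("spec.kind must be 'uniaxial'")
    if not params.incompressible:
        return _solve_uniaxial_penalty(params, fibers, spec)

    i = AXIS_INDEX[spec.load_axis]
    jax, kax = [a for a in range(3) if a != i]
    kappa = params.kappa
    grid = spec.stretch_grid()

    def lateral_imbalance(lt: float, lam: float) -> float:
        f = _diag_f({i: lam, jax: lt, kax: 1.0 / (lam * lt)})
        s = deviatoric_cauchy(DeformationState.create(f, fibers, kappa),
                              params, fibers)
        return s[kax, kax] - s[jax, jax]

    rows = []
    warm = 1.0
    for lam in grid:
        if abs(lam - 1.0) < 1e-15:
            rows.append(_row_from_stress(np.eye(3), np.zeros((3, 3)),
                                         np.zeros((3, 3)), 0.0))
            warm = 1.0
            continue
        lt = _scalar_root(lateral_imbalance, warm, lam)
        f = _diag_f({i: lam, jax: lt, kax: 1.0 / (lam * lt)})
        state = DeformationState.create(f, fibers, kappa)
        s = deviatoric_cauchy(state, params, fibers)
        p = s[jax, jax]  # makes sigma_jj exactly zero
        res = cauchy_stress(state, params, fibers, pressure=p)
        lateral = max(abs(res.cauchy[jax, jax]), abs(res.cauchy[kax, kax]))
        if lateral > 1e-9:
            raise SolverError(f"uniaxial solve at lambda={lam:g}: lateral stress "
                              f"{lateral:.3e} MPa exceeds tolerance")
        rows.append(_row_from_stress(f, res.cauchy, res.nominal, p))
        warm = lt
    return _assemble(spec, params, rows)


def _scalar_root(func, warm: float, lam: float) -> float:
    """Solve func(x, lam) = 0 for the transverse stretch x > 0."""
    try:
        with warnings.catch_warnings():
            # secant may bottom out on machine precision before xtol; the
            # stress-residual check below is the convergence criterion.
            warnings.simplefilter("ignore", RuntimeWarning)
            sol = optimize.root_scalar(func, args=(lam,), x0=warm,
                                       x1=warm * (1.0 + 1e-4), method="secant",
                                       xtol=1e-12, maxiter=100)
        if sol.root is not None and abs(func(sol.root, lam)) < STRESS_TOL:
            return sol.root
    except (ValueError, OverflowError, TypeError):
        pass
    # bracketing fallback: scan for a sign change around the warm start
    xs = np.geomspace(0.3, 2.0, 81)
    vals = np.array([func(x, lam) for x in xs])
    sign = np.sign(vals)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if len(idx) == 0:
        raise SolverError(f"uniaxial solve failed at lambda={lam:g}: "
                          "no sign change found for the lateral-stress residual")
    k = idx[np.argmin(np.abs(xs[idx] - warm))]
    sol = optimize.root_scalar(func, args=(lam,), bracket=(xs[k], xs[k + 1]),
                               method="brentq", xtol=1e-14)
    if not sol.converged:
        raise SolverError(f"uniaxial solve failed at lambda={lam:g}")
    return sol.root


def _solve_uniaxial_penalty(params: MaterialParameters, fibers: FiberArchitecture,
                            spec: ProtocolSpec) -> StressStretchCurve:
    """Penalty-mode uniaxial stress: both transverse stretches are unknowns
    (J is free), lateral Cauchy stresses driven to zero."""
    i = AXIS_INDEX[spec.load_axis]
    jax, kax = [a for a in range(3) if a != i]
    kappa = params.kappa

    def residual(x, lam):
        f = _diag_f({i: lam, jax: x[0], kax: x[1]})
        res = cauchy_stress(DeformationState.create(f, fibers, kappa),
                            params, fibers)
        return [res.cauchy[jax, jax], res.cauchy[kax, kax]]

    rows = []
    warm = np.array([1.0, 1.0])
    for lam in spec.stretch_grid():
        if abs(lam - 1.0) < 1e-15:
            rows.append(_row_from_stress(np.eye(3), np.zeros((3, 3)),
                                         np.zeros((3, 3)), 0.0))
            continue
        sol = optimize.root(residual, warm, args=(lam,), method="hybr",
                            options={"xtol": 1e-13})
        if not sol.success or np.max(np.abs(sol.fun)) > 1e-9:
            raise SolverError(f"penalty uniaxial solve failed at lambda={lam:g}: "
                              f"{sol.message}")
        f = _diag_f({i: lam, jax: sol.x[0], kax: sol.x[1]})
        res = cauchy_stress(DeformationState.create(f, fibers, kappa),
                            params, fibers)
        row = _row_from_stress(f, res.cauchy, res.nominal, np.nan)
        rows.append(row)
        warm = sol.x
    return _assemble(spec, params, rows)


def solve_planar_biaxial(params: MaterialParameters, fibers: FiberArchitecture,
                         spec: ProtocolSpec) -> StressStretchCurve:
    """Planar biaxial stretch in the circumferential-axial plane.

    Both in-plane stretches are imposed, the radial stretch follows from
    incompressibility (lambda_2 = 1/(lambda_1 lambda_3)) and the pressure
    from zero radial Cauchy stress, so every point is a direct evaluation
    — no iteration is involved in incompressible mode.
    """
    if spec.kind not in ("equibiaxial", "planar_biaxial"):
        raise ConfigurationError("spec.kind must be equibiaxial or planar_biaxial")
    grid1 = spec.stretch_grid()
    grid3 = spec.axial_grid()
    kappa = params.kappa

    rows = []
    warm = 1.0
    for l1, l3 in zip(grid1, grid3):
        if params.incompressible:
            l2 = 1.0 / (l1 * l3)
            f = principal_f(l1, l2, l3)
            state = DeformationState.create(f, fibers, kappa)
            s = deviatoric_cauchy(state, params, fibers)
            p = s[1, 1]
            res = cauchy_stress(state, params, fibers, pressure=p)
            rows.append(_row_from_stress(f, res.cauchy, res.nominal, p))
        else:
            def radial_stress(l2, _l1=l1, _l3=l3):
                f = principal_f(_l1, l2, _l3)
                res = cauchy_stress(DeformationState.create(f, fibers, kappa),
                                    params, fibers)
                return res.cauchy[1, 1]

            l2 = _scalar_root(lambda x, lam: radial_stress(x), warm, l1)
            f = principal_f(l1, l2, l3)
            res = cauchy_stress(DeformationState.create(f, fibers, kappa),
                                params, fibers)
            rows.append(_row_from_stress(f, res.cauchy, res.nominal, np.nan))
            warm = l2
    return _assemble(spec, params, rows)


def solve_simple_shear(params: MaterialParameters, fibers: FiberArchitecture,
                       spec: ProtocolSpec) -> StressStretchCurve:
    """Simple shear in the fiber (circumferential-axial) plane.

    F = I + gamma e1 (x) e3 is isochoric, so no kinematic unknowns remain;
    the pressure is fixed by zero radial Cauchy stress.  For gamma != 0
    exactly one fiber family is extended (active) — the normal-stress
    pattern is therefore not symmetric under gamma -> -gamma, while the
    matrix shear response 2*C10*gamma is odd.
    """
    if spec.kind != "simple_shear":
        raise ConfigurationError("spec.kind must be 'simple_shear'")
    if not params.incompressible:
        raise ConfigurationError("simple shear is implemented for the "
                                 "incompressible mode only")
    kappa = params.kappa
    rows = []
    for g in spec.gamma_grid():
        f = simple_shear_f(g)
        state = DeformationState.create(f, fibers, kappa)
        s = deviatoric_cauchy(state, params, fibers)
        p = s[1, 1]
        res = cauchy_stress(state, params, fibers, pressure=p)
        row = _row_from_stress(f, res.cauchy, res.nominal, p)
        row.update({"gamma": g, "p_13": res.nominal[0, 2],
                    "sigma_13": res.cauchy[0, 2]})
        rows.append(row)
    return _assemble(spec, params, rows, shear=True)


def solve_protocol(params: MaterialParameters, fibers: FiberArchitecture,
                   spec: ProtocolSpec) -> StressStretchCurve:
    """Dispatch to the solver matching ``spec.kind``."""
    if spec.kind == "uniaxial":
        return solve_uniaxial(params, fibers, spec)
    if spec.kind in ("equibiaxial", "planar_biaxial"):
        return solve_planar_biaxial(params, fibers, spec)
    return solve_simple_shear(params, fibers, spec)
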