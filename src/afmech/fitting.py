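"""Nonlinear least-squares estimation of HGO constants from stress-stretch data.

The loss is the sum of squared *relative* residuals on nominal stress,
matching the multiplicative noise contract of the synthetic datasets: a
2% load-cell error costs the same at 0.01 MPa as at 10 MPa.  C10 and K1
span more than an order of magnitude between the uniaxial- and
biaxial-derived literature sets, so the optimizer works in log space for
the positive parameters (kappa, when freed, stays linear since 0 is an
admissible value).

Identifiability: the fiber pseudo-invariant I4bar depends only on the
imposed kinematics, not on the material constants, so a dataset in which
no fiber family is ever extended carries no information about K1 or K2.
:func:`fit_parameters` detects this up front and fails loudly instead of
returning an arbitrary point on a flat valley.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import optimize, stats

from .errors import FitFailureError
from .kinematics import compute_invariants
from .materials import FiberArchitecture, MaterialParameters
from .protocols import ProtocolSpec, StressStretchCurve, solve_protocol
from .synthetic import SyntheticDataset

PARAM_NAMES = ("c10", "k1", "k2", "kappa")

#: default box bounds; generous enough to contain both literature sets
DEFAULT_BOUNDS = {
    "c10": (1e-4, 10.0),
    "k1": (1e-3, 100.0),
    "k2": (1.0, 500.0),
    "kappa": (0.0, 1.0 / 3.0),
}

#: floor for the relative-residual denominator, MPa (points at the
#: reference state measure exactly zero stress)
_DENOM_FLOOR = 1e-8


class FitConfig(BaseModel):
    """Configuration of a least-squares fit."""

    model_config = ConfigDict(frozen=True)

    free_parameters: tuple[str, ...] = ("c10", "k1", "k2")
    bounds: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_BOUNDS))
    fixed_values: dict[str, float] = Field(
        default_factory=lambda: {"kappa": 0.0})
    initial: Optional[dict[str, float]] = None
    n_starts: int = Field(default=5, ge=1)
    start_seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "FitConfig":
        for p in self.free_parameters:
            if p not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {p!r}")
            lo, hi = self.bounds.get(p, DEFAULT_BOUNDS[p])
            if not (0.0 <= lo < hi):
                raise ValueError(f"invalid bounds for {p}: ({lo}, {hi})")
        return self

    def bound(self, name: str) -> tuple[float, float]:
        return tuple(self.bounds.get(name, DEFAULT_BOUNDS[name]))


@dataclass
class FitResult:
    """Outcome of :func:`fit_parameters`."""

    estimate: MaterialParameters
    residual: float  # sum of squared relative residuals at the optimum
    n_iterations: int
    converged: bool
    start_index: int
    bound_hits: dict[str, bool]
    n_points: int
    start_diagnostics: list[dict] = field(default_factory=list)
    profile_widths: dict[str, float] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        est = self.estimate
        return {
            "estimate": {"c10_mpa": est.c10, "k1_mpa": est.k1, "k2": est.k2,
                         "kappa": est.kappa},
            "residual": self.residual,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "start_index": self.start_index,
            "bound_hits": self.bound_hits,
            "n_points": self.n_points,
            "profile_widths": self.profile_widths,
        }


@dataclass(frozen=True)
class ProfileResult:
    """Profile of the loss along one parameter (others re-optimized)."""

    parameter: str
    grid: np.ndarray
    losses: np.ndarray
    threshold: float  # loss value bounding the 95% profile interval
    interval: tuple[float, float]

    @property
    def width(self) -> float:
        return self.interval[1] - self.interval[0]


# ---------------------------------------------------------------------------


def _as_curves(data) -> list[StressStretchCurve]:
    if isinstance(data, SyntheticDataset):
        return data.curves
    if isinstance(data, StressStretchCurve):
        return [data]
    return list(data)


def _measured(curve: StressStretchCurve) -> list[tuple[str, np.ndarray]]:
    from .synthetic import _measured_channels
    return [(p_attr, getattr(curve, p_attr))
            for p_attr, _ in _measured_channels(curve)]


def _canonical_order(curves: list[StressStretchCurve]) -> list[StressStretchCurve]:
    """Sort curves by (protocol kind, load axis, first abscissa) so the
    optimizer path does not depend on input ordering."""
    def key(c: StressStretchCurve):
        a = c.abscissa
        return (c.protocol.kind, c.protocol.load_axis, len(c),
                tuple(np.round(a, 12)))
    return sorted(curves, key=key)


def _check_fiber_identifiability(curves, fibers: FiberArchitecture,
                                 kappa: float, free: Sequence[str]) -> None:
    if not ({"k1", "k2"} & set(free)):
        return
    for curve in curves:
        n = len(curve)
        for idx in range(n):
            f = np.diag([curve.lambda_1[idx], curve.lambda_2[idx],
                         curve.lambda_3[idx]])
            if curve.gamma is not None:
                f[0, 2] = curve.gamma[idx]
            inv = compute_invariants(f, fibers, kappa)
            if np.any(inv.i4bar > 1.0):
                return
    raise FitFailureError(
        "no data point extends any fiber family (all I4bar <= 1): "
        "k1/k2 are not identifiable from this dataset")


def _params_from_vector(theta: dict[str, float], label: str) -> MaterialParameters:
    return MaterialParameters(c10=theta["c10"], k1=theta["k1"], k2=theta["k2"],
                              kappa=theta.get("kappa", 0.0), label=label)


def _residual_vector(theta: dict[str, float], curves, fibers) -> np.ndarray:
    params = _params_from_vector(theta, "fit")
    res = []
    for curve in curves:
        model = solve_protocol(params, fibers, curve.protocol)
        for p_attr, measured in _measured(curve):
            predicted = getattr(model, p_attr)
            denom = np.maximum(np.abs(measured), _DENOM_FLOOR)
            res.append((predicted - measured) / denom)
    return np.concatenate(res)


def _make_transform(free: Sequence[str], config: FitConfig):
    """Map free parameters <-> optimizer coordinates (log for positive)."""
    logged = [p != "kappa" for p in free]

    def to_x(theta: dict[str, float]) -> np.ndarray:
        return np.array([np.log(theta[p]) if lg else theta[p]
                         for p, lg in zip(free, logged)])

    def from_x(x: np.ndarray, base: dict[str, float]) -> dict[str, float]:
        theta = dict(base)
        for p, lg, xi in zip(free, logged, x):
            theta[p] = float(np.exp(xi)) if lg else float(xi)
        return theta

    lo = np.array([np.log(config.bound(p)[0]) if lg else config.bound(p)[0]
                   for p, lg in zip(free, logged)])
    hi = np.array([np.log(config.bound(p)[1]) if lg else config.bound(p)[1]
                   for p, lg in zip(free, logged)])
    return to_x, from_x, lo, hi


def _starts(free: Sequence[str], config: FitConfig, lo, hi) -> list[np.ndarray]:
    """First start deterministic at the box midpoint (log-midpoint for the
    positive parameters), remainder log-uniform from the seeded generator."""
    rng = np.random.default_rng(config.start_seed)
    starts = [0.5 * (lo + hi)]
    for _ in range(config.n_starts - 1):
        starts.append(rng.uniform(lo, hi))
    if config.initial is not None:
        to_x, _, _, _ = _make_transform(free, config)
        starts.insert(0, to_x({p: config.initial[p] for p in free}))
    return starts


def fit_parameters(data, fibers: FiberArchitecture,
                   config: FitConfig = FitConfig()) -> FitResult:
    """Estimate the free HGO constants from stress-stretch curves.

    ``data`` may be a :class:`SyntheticDataset`, a single curve, or a list
    of curves (e.g. read from CSV).  Multi-start trust-region least
    squares on the log-transformed free parameters; the best converged
    start wins.

    Raises
    ------
    FitFailureError
        If no start converges, or the data cannot identify the free
        fiber parameters (no fiber family extended anywhere).
    """
    curves = _canonical_order(_as_curves(data))
    n_points = int(sum(len(c) for c in curves))
    free = tuple(config.free_parameters)
    if n_points < len(free):
        raise FitFailureError(
            f"{n_points} data points cannot constrain {len(free)} parameters")

    base = dict(config.fixed_values)
    base.setdefault("kappa", 0.0)
    _check_fiber_identifiability(curves, fibers, base["kappa"], free)

    to_x, from_x, lo, hi = _make_transform(free, config)

    def fun(x):
        return _residual_vector(from_x(x, base), curves, fibers)

    best = None
    diagnostics = []
    for s_idx, x0 in enumerate(_starts(free, config, lo, hi)):
        try:
            sol = optimize.least_squares(fun, np.clip(x0, lo, hi),
                                         bounds=(lo, hi), method="trf",
                                         xtol=1e-12, ftol=1e-12, gtol=1e-12)
            ok = sol.status > 0
            diagnostics.append({"start": s_idx, "cost": float(2 * sol.cost),
                                "status": int(sol.status), "nfev": int(sol.nfev)})
        except Exception as exc:  # solver errors inside residuals
            diagnostics.append({"start": s_idx, "error": repr(exc)})
            continue
        if ok and (best is None or sol.cost < best[1].cost):
            best = (s_idx, sol)

    if best is None:
        raise FitFailureError("no optimizer start converged", diagnostics)

    s_idx, sol = best
    theta = from_x(sol.x, base)
    estimate = _params_from_vector(theta, "fit")
    bound_hits = {}
    for p in free:
        b_lo, b_hi = config.bound(p)
        v = theta[p]
        bound_hits[p] = bool(v - b_lo < 1e-6 * max(1.0, abs(b_lo))
                             or b_hi - v < 1e-6 * max(1.0, abs(b_hi)))
    return FitResult(estimate=estimate, residual=float(np.sum(sol.fun**2)),
                     n_iterations=int(sol.nfev), converged=True,
                     start_index=s_idx, bound_hits=bound_hits,
                     n_points=n_points, start_diagnostics=diagnostics)


def profile_parameter(data, fibers: FiberArchitecture, config: FitConfig,
                      parameter: str, grid: Sequence[float],
                      fit: Optional[FitResult] = None) -> ProfileResult:
    """Profile the loss along ``parameter``, re-optimizing the others.

    The 95% interval is the set of grid values whose profiled loss stays
    under SSR_min * (1 + F(0.95; 1, n-p)/(n-p)) — the standard
    profile-likelihood threshold for nonlinear least squares.  Fit
    failures at individual grid points are recorded as NaN, not fatal.
    """
    if fit is None:
        fit = fit_parameters(data, fibers, config)
    curves = _canonical_order(_as_curves(data))
    remaining = tuple(p for p in config.free_parameters if p != parameter)
    est = fit.estimate
    warm = {"c10": est.c10, "k1": est.k1, "k2": est.k2, "kappa": est.kappa}

    losses = np.full(len(grid), np.nan)
    for i, value in enumerate(grid):
        sub = config.model_copy(update={
            "free_parameters": remaining,
            "fixed_values": {**config.fixed_values, parameter: float(value)},
            "initial": {p: warm[p] for p in remaining},
            "n_starts": 1,
        })
        try:
            res = fit_parameters(data, fibers, sub)
            losses[i] = res.residual
            e = res.estimate
            warm = {"c10": e.c10, "k1": e.k1, "k2": e.k2, "kappa": e.kappa}
        except FitFailureError:
            continue

    n, p = fit.n_points, len(config.free_parameters)
    ssr_min = min(fit.residual, np.nanmin(losses))
    if n > p and ssr_min > 0:
        threshold = ssr_min * (1.0 + stats.f.ppf(0.95, 1, n - p) / (n - p))
    else:
        threshold = ssr_min  # degenerate (noiseless) case: interval collapses
    interval = _threshold_interval(np.asarray(grid, float), losses, threshold)
    return ProfileResult(parameter=parameter, grid=np.asarray(grid, float),
                         losses=losses, threshold=threshold, interval=interval)


def _threshold_interval(grid: np.ndarray, losses: np.ndarray,
                        threshold: float) -> tuple[float, float]:
    """Grid interval where losses <= threshold, edges refined by linear
    interpolation of the loss between neighboring grid points."""
    ok = np.isfinite(losses)
    below = ok & (losses <= threshold)
    if not np.any(below):
        i = int(np.nanargmin(losses))
        return (grid[i], grid[i])
    idx = np.nonzero(below)[0]
    left, right = idx[0], idx[-1]
    x_lo = grid[left]
    if left > 0 and np.isfinite(losses[left - 1]):
        x_lo = np.interp(threshold, [losses[left], losses[left - 1]],
                         [grid[left], grid[left - 1]])
    x_hi = grid[right]
    if right < len(grid) - 1 and np.isfinite(losses[right + 1]):
        x_hi = np.interp(threshold, [losses[right], losses[right + 1]],
                         [grid[right], grid[right + 1]])
    return (float(x_lo), float(x_hi))


def write_fit_result(result: FitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_json_dict(), indent=2,
                                     sort_keys=True) + "\n")
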