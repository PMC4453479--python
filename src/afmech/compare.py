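"""Head-to-head comparison of two HGO parameter sets on identical protocols.

The scientific question: annulus constants fitted to uniaxial tension
tests differ grossly from constants fitted to planar biaxial tests
(C10 0.035 vs 0.85 MPa, K1 0.296 vs 2.8 MPa, K2 65 vs 90).  This module
quantifies the material-point consequence by solving the same protocols
under both sets and reporting per-point stress ratios and
tangent-stiffness ratios (set_b over set_a; conventionally a = uniaxial,
b = biaxial, so ratios > 1 mean the biaxial-derived material is stiffer).

These are material-point metrics.  Published segment-level differences
(ranges of motion, intradiscal pressure) arise from full finite-element
models of a spinal segment and are *not* comparable to the numbers here;
the summary carries a ``scope`` field saying so.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .errors import AfmechError, SolverError
from .materials import FiberArchitecture, MaterialParameters
from .protocols import ProtocolSpec, StressStretchCurve, solve_protocol

#: denominator floor below which a ratio is reported as NaN, MPa
_RATIO_FLOOR = 1e-12

_SCOPE_NOTE = ("material-point comparison on homogeneous protocols; not "
               "comparable to segment-level finite-element quantities")


@dataclass
class ProtocolComparison:
    """Per-point comparison for one protocol."""

    protocol: ProtocolSpec
    abscissa: np.ndarray
    stress_a: np.ndarray  # loading-direction nominal stress, set a
    stress_b: np.ndarray
    stress_ratio: np.ndarray  # b / a, NaN where |a| < floor
    tangent_a: np.ndarray  # centered-secant d(stress)/d(abscissa)
    tangent_b: np.ndarray
    tangent_ratio: np.ndarray


class ProtocolSummary(BaseModel):
    protocol: str
    load_axis: str
    n_points: int
    max_stress_ratio: float
    median_stress_ratio: float
    max_tangent_ratio: float
    median_tangent_ratio: float
    median_stress_pct_difference: float


class ComparisonSummary(BaseModel):
    """JSON summary schema of a two-parameter-set comparison."""

    model_config = ConfigDict(extra="forbid")

    label_a: str
    label_b: str
    ratio_convention: str
    scope: str
    package_version: str
    protocols: list[ProtocolSummary]


@dataclass
class ComparisonReport:
    set_a: MaterialParameters
    set_b: MaterialParameters
    comparisons: list[ProtocolComparison]
    curves_a: list[StressStretchCurve] = field(default_factory=list)
    curves_b: list[StressStretchCurve] = field(default_factory=list)

    def summary(self) -> ComparisonSummary:
        rows = []
        for comp in self.comparisons:
            sr = comp.stress_ratio[np.isfinite(comp.stress_ratio)]
            tr = comp.tangent_ratio[np.isfinite(comp.tangent_ratio)]
            rows.append(ProtocolSummary(
                protocol=comp.protocol.kind,
                load_axis=comp.protocol.load_axis,
                n_points=len(comp.abscissa),
                max_stress_ratio=float(np.max(sr)) if sr.size else float("nan"),
                median_stress_ratio=float(np.median(sr)) if sr.size else float("nan"),
                max_tangent_ratio=float(np.max(tr)) if tr.size else float("nan"),
                median_tangent_ratio=float(np.median(tr)) if tr.size else float("nan"),
                median_stress_pct_difference=(
                    float(100.0 * (np.median(sr) - 1.0)) if sr.size else float("nan")),
            ))
        return ComparisonSummary(
            label_a=self.set_a.label, label_b=self.set_b.label,
            ratio_convention="set_b / set_a",
            scope=_SCOPE_NOTE,
            package_version=__version__,
            protocols=rows,
        )

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for comp in self.comparisons:
            frames.append(pd.DataFrame({
                "protocol": np.full(len(comp.abscissa), comp.protocol.kind),
                "load_axis": np.full(len(comp.abscissa), comp.protocol.load_axis),
                "abscissa": comp.abscissa,
                "stress_a_MPa": comp.stress_a,
                "stress_b_MPa": comp.stress_b,
                "stress_ratio": comp.stress_ratio,
                "tangent_a_MPa": comp.tangent_a,
                "tangent_b_MPa": comp.tangent_b,
                "tangent_ratio": comp.tangent_ratio,
            }))
        return pd.concat(frames, ignore_index=True)


def centered_secant(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Centered-secant derivative on a (possibly non-uniform) grid;
    one-sided at the ends.  np.gradient implements exactly this."""
    return np.gradient(y, x)


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full_like(num, np.nan, dtype=float)
    ok = np.abs(den) > _RATIO_FLOOR
    out[ok] = num[ok] / den[ok]
    return out


def run_comparison(set_a: MaterialParameters, set_b: MaterialParameters,
                   fibers: FiberArchitecture,
                   specs: list[ProtocolSpec]) -> ComparisonReport:
    """Solve every protocol under both sets and compute per-point ratios.

    Loading-direction nominal stress is the compared measure; tangent
    stiffness is its centered-secant slope on the imposed grid.  Solver
    failures are re-raised labelled with the failing set.
    """
    comparisons, curves_a, curves_b = [], [], []
    for spec in specs:
        solved = {}
        for tag, params in (("a", set_a), ("b", set_b)):
            try:
                solved[tag] = solve_protocol(params, fibers, spec)
            except AfmechError as exc:
                raise SolverError(
                    f"set_{tag} ({params.label!r}) failed on protocol "
                    f"{spec.kind}: {exc}") from exc
        ca, cb = solved["a"], solved["b"]
        x = ca.abscissa
        sa, sb = ca.loading_nominal, cb.loading_nominal
        ta, tb = centered_secant(x, sa), centered_secant(x, sb)
        comparisons.append(ProtocolComparison(
            protocol=spec, abscissa=x, stress_a=sa, stress_b=sb,
            stress_ratio=_safe_ratio(sb, sa),
            tangent_a=ta, tangent_b=tb,
            tangent_ratio=_safe_ratio(tb, ta)))
        curves_a.append(ca)
        curves_b.append(cb)
    return ComparisonReport(set_a=set_a, set_b=set_b, comparisons=comparisons,
                            curves_a=curves_a, curves_b=curves_b)


def write_report(report: ComparisonReport, outdir: str | Path,
                 plot: bool = False) -> dict[str, Path]:
    """Write per-point CSV + summary JSON (+ optional PNG plot).

    Output is byte-stable for fixed inputs: no timestamps, sorted JSON
    keys, shortest-repr floats.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    csv_path = outdir / "comparison_points.csv"
    report.to_frame().to_csv(csv_path, index=False, lineterminator="\n")
    out["points_csv"] = csv_path

    json_path = outdir / "comparison_summary.json"
    json_path.write_text(json.dumps(report.summary().model_dump(),
                                    indent=2, sort_keys=True) + "\n")
    out["summary_json"] = json_path

    if plot:
        out["plot_png"] = _plot(report, outdir / "comparison.png")
    return out


def _plot(report: ComparisonReport, path: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.6), constrained_layout=True)
    for comp in report.comparisons:
        lbl = f"{comp.protocol.kind} ({comp.protocol.load_axis})"
        axes[0].plot(comp.abscissa, comp.stress_a, "--", label=f"{lbl}, a")
        axes[0].plot(comp.abscissa, comp.stress_b, "-", label=f"{lbl}, b")
        axes[1].plot(comp.abscissa, comp.stress_ratio, label=lbl)
    axes[0].set_xlabel("stretch / shear")
    axes[0].set_ylabel("nominal stress [MPa]")
    axes[0].set_yscale("symlog", linthresh=1e-3)
    axes[0].legend(fontsize=6)
    axes[1].set_xlabel("stretch / shear")
    axes[1].set_ylabel("stress ratio b/a")
    axes[1].legend(fontsize=6)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def load_summary(path: str | Path) -> ComparisonSummary:
    """Read and validate a summary JSON against the packaged schema."""
    return ComparisonSummary.model_validate_json(Path(path).read_text())


def export_summary_schema(path: str | Path) -> None:
    """Write the JSON schema of :class:`ComparisonSummary` (the shipped
    ``schemas/comparison_summary.schema.json`` is generated this way)."""
    Path(path).write_text(json.dumps(ComparisonSummary.model_json_schema(),
                                     indent=2, sort_keys=True) + "\n")
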