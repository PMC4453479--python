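"""Synthetic stress-stretch datasets with multiplicative Gaussian noise.

Emulates stretch-controlled uniaxial and planar-biaxial tension tests of
annulus specimens: the stretch grids are exact (stretch-controlled rigs),
while every *measured* stress channel is perturbed multiplicatively,

    P_measured = P_model * (1 + eps),   eps ~ N(0, sigma_rel), iid per point.

Multiplicative noise is the realistic contract here because the stress
spans orders of magnitude across the toe-to-exponential transition, so a
constant relative error — not a constant absolute error — matches what
load cells deliver.  The matching Cauchy component is scaled by the same
factor (Cauchy is derived from the measured force and the known stretch,
so its relative error is identical).

Only the load-bearing channels of each protocol are treated as measured:
the loading axis for uniaxial, both in-plane channels (independently) for
biaxial, the 13 channel for shear.  Zero-by-construction channels stay
exactly zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .errors import ConfigurationError
from .materials import (FiberArchitecture, MaterialConfig, MaterialParameters,
                        biaxial_reference, uniaxial_reference)
from .protocols import ProtocolSpec, StressStretchCurve, solve_protocol


class NoiseModel(BaseModel):
    """Multiplicative Gaussian measurement noise on stress channels."""

    model_config = ConfigDict(frozen=True)

    kind: Literal["multiplicative-gaussian"] = "multiplicative-gaussian"
    sigma_rel: float = Field(default=0.02, ge=0.0)
    seed: int = 0


@dataclass
class SyntheticDataset:
    """Noisy curves plus the generating ground truth."""

    curves: list[StressStretchCurve]
    model_curves: list[StressStretchCurve]
    true_params: Optional[MaterialParameters]
    noise: NoiseModel
    generator_version: str = __version__


def _measured_channels(curve: StressStretchCurve) -> list[tuple[str, str]]:
    """(nominal attr, cauchy attr) pairs of the channels a rig measures."""
    kind = curve.protocol.kind
    if kind == "uniaxial":
        ax = {"circumferential": ("p_11", "sigma_11"),
              "radial": ("p_22", "sigma_22"),
              "axial": ("p_33", "sigma_33")}[curve.protocol.load_axis]
        return [ax]
    if kind == "simple_shear":
        return [("p_13", "sigma_13")]
    return [("p_11", "sigma_11"), ("p_33", "sigma_33")]


def generate_dataset(true_params: MaterialParameters, fibers: FiberArchitecture,
                     specs: list[ProtocolSpec], noise: NoiseModel) -> SyntheticDataset:
    """Solve every protocol under ``true_params`` and apply seeded noise.

    Deterministic given ``noise.seed``: the same seed reproduces the
    dataset bit for bit.  Stretch columns are never perturbed.
    """
    if not specs:
        raise ConfigurationError("specs must be non-empty")
    rng = np.random.default_rng(noise.seed)
    model_curves: list[StressStretchCurve] = []
    noisy_curves: list[StressStretchCurve] = []
    for spec in specs:
        clean = solve_protocol(true_params, fibers, spec)
        noisy = StressStretchCurve.from_frame(clean.to_frame())
        for p_attr, s_attr in _measured_channels(clean):
            eps = rng.normal(0.0, noise.sigma_rel, size=len(clean))
            setattr(noisy, p_attr, getattr(clean, p_attr) * (1.0 + eps))
            setattr(noisy, s_attr, getattr(clean, s_attr) * (1.0 + eps))
        model_curves.append(clean)
        noisy_curves.append(noisy)
    return SyntheticDataset(curves=noisy_curves, model_curves=model_curves,
                            true_params=true_params, noise=noise)


# ---------------------------------------------------------------------------
# on-disk bundle: one CSV per curve + a JSON manifest
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, outdir: str | Path,
                  stem: str = "curve") -> Path:
    """Write the dataset bundle; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for i, curve in enumerate(dataset.curves):
        name = f"{stem}_{i:02d}_{curve.protocol.kind}.csv"
        curve.to_csv(outdir / name)
        files.append(name)
    manifest = {
        "generator_version": dataset.generator_version,
        "noise": dataset.noise.model_dump(),
        "true_params": (MaterialConfig.from_params(dataset.true_params).model_dump(
            exclude_none=True) if dataset.true_params is not None else None),
        "files": files,
    }
    path = outdir / f"{stem}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def read_dataset(manifest_path: str | Path) -> SyntheticDataset:
    """Read a dataset bundle back; model curves are re-solved from the
    manifest's true parameters when available (empty otherwise)."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    curves = [StressStretchCurve.from_csv(manifest_path.parent / f)
              for f in manifest["files"]]
    noise = NoiseModel.model_validate(manifest["noise"])
    true_params = None
    model_curves: list[StressStretchCurve] = []
    if manifest.get("true_params") is not None:
        cfg = MaterialConfig.model_validate(manifest["true_params"])
        true_params = cfg.to_params()
        fibers = cfg.to_fibers()
        model_curves = [solve_protocol(true_params, fibers, c.protocol)
                        for c in curves]
    return SyntheticDataset(curves=curves, model_curves=model_curves,
                            true_params=true_params, noise=noise,
                            generator_version=manifest["generator_version"])


#: fixed fixture seeds (arbitrary, frozen once)
FIXTURE_SEED_UNIAXIAL = 20101
FIXTURE_SEED_BIAXIAL = 20103


def make_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Write the packaged fixture bundles used by tests and docs.

    * ``uniaxial_truth.json`` / ``biaxial_truth.json``: the two reference
      parameter sets.
    * a uniaxial-protocol dataset generated from the uniaxial set and a
      planar-biaxial dataset from the biaxial set, fixed seeds, 2% noise.

    Re-running reproduces identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    for name, (params, fibers) in (("uniaxial", uniaxial_reference()),
                                   ("biaxial", biaxial_reference())):
        truth = outdir / f"{name}_truth.json"
        truth.write_text(json.dumps(
            MaterialConfig.from_params(params).model_dump(exclude_none=True),
            indent=2, sort_keys=True) + "\n")
        out[f"{name}_truth"] = truth

    u_params, u_fibers = uniaxial_reference()
    out["uniaxial_dataset"] = write_dataset(
        generate_dataset(u_params, u_fibers,
                         [ProtocolSpec(kind="uniaxial")],
                         NoiseModel(seed=FIXTURE_SEED_UNIAXIAL)),
        outdir, stem="uniaxial")

    b_params, b_fibers = biaxial_reference()
    out["biaxial_dataset"] = write_dataset(
        generate_dataset(b_params, b_fibers,
                         [ProtocolSpec(kind="equibiaxial")],
                         NoiseModel(seed=FIXTURE_SEED_BIAXIAL)),
        outdir, stem="biaxial")
    return out
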