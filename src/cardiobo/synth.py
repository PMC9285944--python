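"""Synthetic subjects: observations generated from the toy forward model.

A synthetic subject is defined by a ground-truth scaling vector theta_true
and a geometry; the observation is what a real study would measure -- the
8 mmHg cavity volume, 24 regional circumferential strains (with seeded
regional heterogeneity and optional additive Gaussian measurement noise) and
the load-free volume proxy V0hat -- plus a truth sidecar that only tests may
read (estimation code never sees it).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .constitutive import as_theta
from .forward import CylindricalLVModel, GeometrySpec, N_REGIONS, toy_geometry
from .klotz import SubjectObservation

__all__ = ["SubjectSpec", "make_subject", "make_fixture_suite", "GenerationError"]


class GenerationError(RuntimeError):
    """theta_true lies in the simulator's crash region."""


@dataclass(frozen=True)
class SubjectSpec:
    """Recipe for one synthetic subject.

    Noise defaults are small relative to the signal (strains ~0.15, volumes
    ~150 mL) so that recovery experiments remain informative.
    """

    theta_true: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    geometry: str | GeometrySpec = "toyA"
    reference: str = "in_vivo_gao"
    strain_noise_sd: float = 0.005
    volume_noise_sd_ml: float = 1.0
    h_spread: float = 0.05
    pressure_mmhg: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        as_theta(self.theta_true)
        if min(self.strain_noise_sd, self.volume_noise_sd_ml, self.h_spread) < 0:
            raise ValueError("noise and spread parameters must be >= 0")

    def resolved_geometry(self) -> GeometrySpec:
        g = self.geometry if isinstance(self.geometry, GeometrySpec) else toy_geometry(self.geometry)
        return g


def make_subject(spec: SubjectSpec) -> tuple[SubjectObservation, GeometrySpec, dict]:
    """Generate one observation plus the geometry used and a truth record."""
    rng = np.random.default_rng(spec.seed)
    base = spec.resolved_geometry()
    h = np.clip(1.0 + spec.h_spread * rng.standard_normal(N_REGIONS), 0.5, 1.5)
    geom = replace(base, heterogeneity=tuple(float(x) for x in h))
    model = CylindricalLVModel(geom)
    res = model.inflate(spec.theta_true, spec.reference, spec.pressure_mmhg)
    if res.crashed:
        raise GenerationError(
            f"theta_true={spec.theta_true} crashes the simulator at "
            f"{spec.pressure_mmhg} mmHg; choose a stiffer ground truth"
        )
    v8 = res.volume_ml + spec.volume_noise_sd_ml * rng.standard_normal()
    strains = res.strains + spec.strain_noise_sd * rng.standard_normal(N_REGIONS)
    # zero-pressure (early-diastolic) cavity volume as the load-free proxy
    v0hat = model.inflate(spec.theta_true, spec.reference, 0.0).volume_ml
    obs = SubjectObservation(
        v8_ml=float(v8),
        strains=strains,
        v0hat_ml=float(v0hat),
        p_star_mmhg=spec.pressure_mmhg,
    )
    truth = {
        "theta_true": list(map(float, spec.theta_true)),
        "reference": spec.reference,
        "geometry_label": geom.label,
        "noise_free_v8_ml": float(res.volume_ml),
        "seed": spec.seed,
    }
    return obs, geom, truth


def make_fixture_suite(
    n_subjects: int,
    seed: int,
    outdir: str | Path | None = None,
    noise_free: bool = False,
):
    """A suite of distinct synthetic subjects (geometries cycle toyA..toyD,
    ground truths spread over the interior of the default search box).

    Returns a manifest dict; if ``outdir`` is given, writes one observation
    JSON, one truth JSON and one geometry YAML per subject plus
    ``manifest.yaml``.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(seed)
    labels = [chr(ord("A") + i) for i in range(n_subjects)]
    geoms = ["toyA", "toyB", "toyC", "toyD"]
    entries = []
    for i, lab in enumerate(labels):
        theta = rng.uniform([0.7, 0.7, 0.8, 0.5], [2.2, 2.2, 2.0, 2.0])
        spec = SubjectSpec(
            theta_true=tuple(np.round(theta, 3)),
            geometry=geoms[i % len(geoms)],
            strain_noise_sd=0.0 if noise_free else 0.005,
            volume_noise_sd_ml=0.0 if noise_free else 1.0,
            seed=int(rng.integers(2**31 - 1)),
        )
        obs, geom, truth = make_subject(spec)
        entry = {"label": lab, "spec": spec, "obs": obs, "geom": geom, "truth": truth}
        entries.append(entry)
    manifest = {"n_subjects": n_subjects, "seed": seed, "subjects": entries}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        listing = []
        for e in entries:
            stem = f"subject_{e['label']}"
            e["obs"].to_json(outdir / f"{stem}.obs.json")
            e["geom"].to_yaml(outdir / f"{stem}.geom.yaml")
            with open(outdir / f"{stem}.truth.json", "w") as fh:
                json.dump(e["truth"], fh, indent=1)
            listing.append(
                {
                    "label": e["label"],
                    "observation": f"{stem}.obs.json",
                    "geometry": f"{stem}.geom.yaml",
                    "truth": f"{stem}.truth.json",
                    "theta_true": e["truth"]["theta_true"],
                }
            )
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(
                {"n_subjects": n_subjects, "seed": seed, "subjects": listing}, fh
            )
    return manifest
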