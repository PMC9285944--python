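"""Run configuration (schema-validated YAML) and result serialisation."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .bo import BOConfig, BOState, DEFAULT_BOX
from .constitutive import descale, reference_vector, uniaxial_curve
from .hgo import HGOConfig, HGOResult

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "write_results"]

log = logging.getLogger("cardiobo")


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BOSection(_Strict):
    box: list[list[float]] = Field(default_factory=lambda: [list(b) for b in DEFAULT_BOX])
    log_scale: bool = False
    n_init: int = 40
    n_iter: int = 500
    surrogate: str = "target"
    objective: str = "fO2_klotz"
    v30_source: str = "emulator"
    reference: str = "in_vivo_gao"
    refit_every: int = 10
    gp_restarts: int = 8
    gp_refit_restarts: int = 2
    acq_starts: int = 64
    acq_refine: int = 8
    acq_maxfev: int = 48

    def to_bo_config(self, seed: int) -> BOConfig:
        d = self.model_dump()
        d["box"] = tuple(tuple(b) for b in d["box"])
        return BOConfig(seed=seed, **d)


class HGOSection(_Strict):
    variant: str = "updated"
    reference: str | None = None
    step_budget: int = 60

    def to_hgo_config(self) -> HGOConfig:
        return HGOConfig(**self.model_dump())


class SubjectSection(_Strict):
    observation: str | None = None       # path to an observation JSON
    geometry: str = "toyA"               # fixture label or geometry YAML path
    theta_true: list[float] | None = None
    strain_noise_sd: float = 0.005
    volume_noise_sd_ml: float = 1.0
    h_spread: float = 0.05


class V30Section(_Strict):
    n_train: int = 200
    v0_range_ml: list[float] = Field(default_factory=lambda: [60.0, 120.0])
    model_path: str | None = None


class RunConfig(_Strict):
    seed: int = 0
    output_dir: str = "cardiobo_out"
    log_level: str = "INFO"
    subject: SubjectSection = Field(default_factory=SubjectSection)
    bo: BOSection = Field(default_factory=BOSection)
    hgo: HGOSection = Field(default_factory=HGOSection)
    v30: V30Section = Field(default_factory=V30Section)


def load_config(path) -> RunConfig:
    """Parse and schema-validate a YAML run configuration.

    Unknown keys are rejected by name; defaults are filled for everything
    else.  The effective configuration should be echoed into the output
    directory by the caller (see :func:`save_config`).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig(**raw)
    except ValidationError as err:
        details = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors()
        )
        raise ConfigError(f"invalid run configuration: {details}") from None


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)


def write_results(
    state: BOState,
    outdir,
    theta_best=None,
    reference: str = "in_vivo_gao",
    hgo_result: HGOResult | None = None,
    bo_summary: dict | None = None,
) -> dict:
    """Write the trace CSV, summary JSON and stress-stretch curve CSV.

    Returns the summary dictionary.  The trace has one row per forward
    evaluation; the summary reports the incumbent minimum, the evaluation
    index where it was attained, the crash count and -- when a baseline
    result is supplied -- the paired convergence comparison.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    trace = state.trace()
    trace.to_csv(outdir / "trace.csv", index=False)

    summary = {
        "ymin": state.ymin,
        "imin": state.imin,
        "n_evaluations": state.n_evaluations,
        "crash_count": state.crash_count,
    }
    if theta_best is None and state.n_evaluations:
        theta_best = state.theta_best
    if theta_best is not None:
        summary["theta_best"] = [float(v) for v in theta_best]
    if bo_summary:
        summary.update(bo_summary)
    if hgo_result is not None:
        summary["hgo"] = hgo_result.to_dict()
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)

    if theta_best is not None:
        params = descale(theta_best, reference_vector(reference))
        lam = np.linspace(1.0, 1.3, 61)
        rows = []
        for direction in ("myocyte", "sheet"):
            stress = uniaxial_curve(params, direction, lam)
            for l, s in zip(lam, stress):
                rows.append(
                    {"lambda": l, "stress_kPa": s, "direction": direction,
                     "label": "estimate"}
                )
        pd.DataFrame(rows).to_csv(outdir / "curves.csv", index=False)
    return summary
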