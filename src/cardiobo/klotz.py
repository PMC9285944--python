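"""Klotz pressure-volume law, high-pressure volume prediction and objectives.

The Klotz law is an empirical, population-wide relationship between the LV
filling pressure and the *normalised* end-diastolic volume

    Vnorm = (V - V0) / (V30 - V0),        P = A * Vnorm**B,

with fitted coefficients A = 27.78 mmHg and B = 2.76.  Inverted at the
assumed in vivo end-diastolic pressure P* (8 mmHg by population default) it
predicts the unobservable 30 mmHg volume from the measured volume V* and the
load-free volume proxy V0hat (the early-diastolic volume):

    V30hat = V0hat + (V* - V0hat) / (P*/A)**(1/B).

Three least-squares objectives compare a forward simulation with a subject
observation; each also returns its vector of partial error terms, which is
what the partial-error surrogate variant of the optimiser models:

  fO1       = (V - V*)^2            + sum_i (eps_i - eps_i*)^2      (K*=25)
  fO2       = (V - V*)^2 / V*       + sum_i (eps_i - eps_i*)^2      (K*=25)
  fO2_klotz = ((V8-V8*)/V8*)^2 + sum_i (eps_i - eps_i*)^2
              + ((V30 - V30hat)/V30hat)^2                           (K*=26)

(The fO2 volume term divides by V*, not V*^2 -- the two relative-volume
conventions are deliberately non-uniform and implemented exactly as stated.)
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .forward import N_REGIONS, SimulatorResult

__all__ = [
    "KlotzParams",
    "SubjectObservation",
    "klotz_normalised_volume",
    "klotz_pressure",
    "predict_v30",
    "objective_fO1",
    "objective_fO2",
    "objective_fO2_klotz",
]


class ObjectiveUndefinedError(ValueError):
    """The objective was requested for a crashed simulation."""


@dataclass(frozen=True)
class KlotzParams:
    """Klotz-law coefficients: A in mmHg, B dimensionless."""

    A: float = 27.78
    B: float = 2.76

    def __post_init__(self) -> None:
        if self.A <= 0 or self.B <= 0:
            raise ValueError("Klotz coefficients must be positive")


@dataclass(frozen=True)
class SubjectObservation:
    """Per-subject measurement record.

    ``v8_ml``: LV cavity volume (mL) at the assumed ED pressure
    ``p_star_mmhg``; ``strains``: 24 regional circumferential strains;
    ``v0hat_ml``: early-diastolic volume, used as the load-free volume proxy.
    """

    v8_ml: float
    strains: np.ndarray
    v0hat_ml: float
    p_star_mmhg: float = 8.0

    def __post_init__(self) -> None:
        s = np.asarray(self.strains, dtype=float)
        if s.shape != (N_REGIONS,):
            raise ValueError(f"observation needs exactly {N_REGIONS} strains")
        object.__setattr__(self, "strains", s)
        if not (self.v8_ml > self.v0hat_ml > 0):
            raise ValueError("require v8_ml > v0hat_ml > 0")
        if self.p_star_mmhg <= 0:
            raise ValueError("p_star_mmhg must be positive")

    def to_json(self, path) -> None:
        d = {
            "v8_ml": self.v8_ml,
            "strains": list(map(float, self.strains)),
            "p_star_mmhg": self.p_star_mmhg,
            "v0hat_ml": self.v0hat_ml,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @staticmethod
    def from_json(path) -> "SubjectObservation":
        with open(path) as fh:
            d = json.load(fh)
        return SubjectObservation(
            v8_ml=d["v8_ml"],
            strains=np.asarray(d["strains"], dtype=float),
            v0hat_ml=d["v0hat_ml"],
            p_star_mmhg=d.get("p_star_mmhg", 8.0),
        )


def klotz_normalised_volume(v_ml: float, v0_ml: float, v30_ml: float) -> float:
    """(V - V0) / (V30 - V0)."""
    if v30_ml <= v0_ml:
        raise ValueError("require V30 > V0 for normalisation")
    return (v_ml - v0_ml) / (v30_ml - v0_ml)


def klotz_pressure(vnorm: float, kp: KlotzParams = KlotzParams()) -> float:
    """Pressure (mmHg) on the Klotz curve at normalised volume vnorm."""
    if vnorm < 0:
        raise ValueError("normalised volume must be non-negative")
    return kp.A * vnorm**kp.B


def predict_v30(obs: SubjectObservation, kp: KlotzParams = KlotzParams()) -> float:
    """Klotz-predicted 30 mmHg volume (mL) from V*, P* and the V0 proxy."""
    if obs.p_star_mmhg >= kp.A:
        warnings.warn(
            "P* >= A: normalised volume >= 1, extrapolating the Klotz law",
            stacklevel=2,
        )
    vnorm_star = (obs.p_star_mmhg / kp.A) ** (1.0 / kp.B)
    return obs.v0hat_ml + (obs.v8_ml - obs.v0hat_ml) / vnorm_star


def _check_success(sim: SimulatorResult) -> None:
    if sim.crashed:
        raise ObjectiveUndefinedError("objective undefined for a crashed simulation")


def objective_fO1(
    sim: SimulatorResult, obs: SubjectObservation
) -> tuple[float, np.ndarray]:
    """Absolute-volume objective; partials = [volume term, 24 strain terms]."""
    _check_success(sim)
    parts = np.empty(N_REGIONS + 1)
    parts[0] = (sim.volume_ml - obs.v8_ml) ** 2
    parts[1:] = (sim.strains - obs.strains) ** 2
    return float(parts.sum()), parts


def objective_fO2(
    sim: SimulatorResult, obs: SubjectObservation
) -> tuple[float, np.ndarray]:
    """Volume-weighted objective; the volume term is divided by V*."""
    _check_success(sim)
    parts = np.empty(N_REGIONS + 1)
    parts[0] = (sim.volume_ml - obs.v8_ml) ** 2 / obs.v8_ml
    parts[1:] = (sim.strains - obs.strains) ** 2
    return float(parts.sum()), parts


def objective_fO2_klotz(
    sim8: SimulatorResult,
    v30_ml: float,
    obs: SubjectObservation,
    kp: KlotzParams = KlotzParams(),
) -> tuple[float, np.ndarray]:
    """Klotz-penalised objective; partials = [V8 term, 24 strain terms, V30 term].

    ``v30_ml`` is the simulated or emulated 30 mmHg volume; the reference
    value it is penalised against is the Klotz prediction from the subject
    observation.
    """
    _check_success(sim8)
    v30hat = predict_v30(obs, kp)
    parts = np.empty(N_REGIONS + 2)
    parts[0] = ((sim8.volume_ml - obs.v8_ml) / obs.v8_ml) ** 2
    parts[1:-1] = (sim8.strains - obs.strains) ** 2
    parts[-1] = ((v30_ml - v30hat) / v30hat) ** 2
    return float(parts.sum()), parts
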