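"""Hemodynamic reference models linking vessel mechanics, pulse wave velocity,
pulse transit time, and blood pressure.

The models here serve two roles: as reference regressions against which fitted
models are compared, and as the ground-truth link used by the synthetic cohort
generator (:mod:`radarbp.sim`).

Units are SI except blood pressure, which is in mmHg throughout (so the
pressure coefficient ``zeta`` is per mmHg and the models compose without unit
conversion).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Any

import numpy as np

__all__ = [
    "VesselProperties",
    "BPModelParams",
    "SubjectProfile",
    "moens_korteweg_pwv",
    "hughes_modulus",
    "bp_from_pwv",
    "bp_from_ptt",
    "ptt_from_bp",
    "bp_params_for_dbp_range",
]


@dataclass(frozen=True)
class VesselProperties:
    """Mechanical description of an arterial segment.

    Attributes
    ----------
    elastic_modulus_zero_pressure : float
        Vessel-wall elastic modulus at zero transmural pressure, in Pa.
    wall_thickness : float
        Vessel wall thickness, in m.
    inner_radius : float
        Vessel inner radius, in m.
    blood_density : float
        Blood density, in kg/m^3.
    pressure_coefficient : float
        Exponential stiffening coefficient, per mmHg.
    """

    elastic_modulus_zero_pressure: float
    wall_thickness: float
    inner_radius: float
    blood_density: float = 1060.0
    pressure_coefficient: float = 0.017

    def __post_init__(self) -> None:
        for name in (
            "elastic_modulus_zero_pressure",
            "wall_thickness",
            "inner_radius",
            "blood_density",
            "pressure_coefficient",
        ):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"VesselProperties.{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class BPModelParams:
    """Coefficients of the BP-vs-PWV and BP-vs-PTT relations.

    ``a`` (mmHg s^2/m^2) and ``b`` (mmHg) parameterize BP = a * PWV**2 + b.
    ``k1`` (mmHg s) and ``k2`` (mmHg) parameterize BP = k1 / PTT + k2.
    """

    a: float = 4.0
    b: float = 60.0
    k1: float = 16.8
    k2: float = 0.0

    def __post_init__(self) -> None:
        if not self.k1 > 0:
            raise ValueError(f"k1 must be > 0 so BP decreases with PTT, got {self.k1!r}")
        if not self.a > 0:
            raise ValueError(f"a must be > 0, got {self.a!r}")


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject description used by the simulator and feature pipeline.

    ``arm_length`` is the arterial path length from heart to wrist in meters.
    ``baseline_dbp_range`` / ``baseline_sbp_range`` bound the subject's
    resting-to-active blood-pressure excursion in mmHg.
    """

    subject_id: str
    age: float
    arm_length: float
    bp_params: BPModelParams
    baseline_sbp_range: tuple[float, float] = (105.0, 135.0)
    baseline_dbp_range: tuple[float, float] = (65.0, 90.0)

    def __post_init__(self) -> None:
        if not (0.3 <= self.arm_length <= 1.0):
            raise ValueError(f"arm_length must be in [0.3, 1.0] m, got {self.arm_length!r}")
        for name in ("baseline_sbp_range", "baseline_dbp_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be ordered (low <= high), got ({lo}, {hi})")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["baseline_sbp_range"] = list(self.baseline_sbp_range)
        d["baseline_dbp_range"] = list(self.baseline_dbp_range)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SubjectProfile":
        d = dict(d)
        d["bp_params"] = BPModelParams(**d["bp_params"])
        d["baseline_sbp_range"] = tuple(d["baseline_sbp_range"])
        d["baseline_dbp_range"] = tuple(d["baseline_dbp_range"])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SubjectProfile":
        return cls.from_dict(json.loads(text))


def moens_korteweg_pwv(elastic_modulus: float, vessel: VesselProperties) -> float:
    """Pulse wave velocity from wall elasticity and vessel geometry.

    PWV = sqrt(E * h0 / (2 * rho * R0)), in m/s. Strictly increasing in E.
    """
    if not (elastic_modulus > 0 and math.isfinite(elastic_modulus)):
        raise ValueError(f"elastic modulus must be strictly positive, got {elastic_modulus!r}")
    return math.sqrt(
        elastic_modulus
        * vessel.wall_thickness
        / (2.0 * vessel.blood_density * vessel.inner_radius)
    )


def hughes_modulus(pressure_mmhg: float, vessel: VesselProperties) -> float:
    """Arterial elastic modulus at transmural pressure P: E = E0 * exp(zeta * P)."""
    return vessel.elastic_modulus_zero_pressure * math.exp(
        vessel.pressure_coefficient * pressure_mmhg
    )


def bp_from_pwv(pwv: float, params: BPModelParams) -> float:
    """Blood pressure from pulse wave velocity: BP = a * PWV**2 + b (mmHg)."""
    if pwv < 0:
        raise ValueError(f"pwv must be non-negative, got {pwv!r}")
    return params.a * pwv**2 + params.b


def bp_from_ptt(ptt, params: BPModelParams):
    """Blood pressure from pulse transit time: BP = k1 / PTT + k2 (mmHg).

    Accepts scalars or arrays; PTT must be strictly positive.
    """
    ptt_arr = np.asarray(ptt, dtype=float)
    if np.any(ptt_arr <= 0):
        raise ValueError("ptt must be strictly positive")
    out = params.k1 / ptt_arr + params.k2
    return float(out) if np.isscalar(ptt) or ptt_arr.ndim == 0 else out


def ptt_from_bp(bp, params: BPModelParams):
    """Inverse of :func:`bp_from_ptt`: PTT = k1 / (BP - k2), in seconds.

    Requires BP > k2. Round trips with :func:`bp_from_ptt` to machine
    precision.
    """
    bp_arr = np.asarray(bp, dtype=float)
    if np.any(bp_arr <= params.k2):
        raise ValueError(f"bp must exceed k2={params.k2} for a positive transit time")
    out = params.k1 / (bp_arr - params.k2)
    return float(out) if np.isscalar(bp) or bp_arr.ndim == 0 else out


def bp_params_for_dbp_range(
    dbp_range: tuple[float, float],
    ptt_range: tuple[float, float] = (0.15, 0.30),
    a: float = 4.0,
    b: float = 60.0,
) -> BPModelParams:
    """Choose (k1, k2) so the DBP range maps onto the given PTT range.

    The highest DBP maps to the shortest PTT and vice versa, consistent with
    the inverse BP-PTT relationship. Used to assign plausible
    subject-dependent constants in the simulator.
    """
    dbp_lo, dbp_hi = dbp_range
    ptt_lo, ptt_hi = ptt_range
    if not (dbp_lo < dbp_hi and 0 < ptt_lo < ptt_hi):
        raise ValueError("ranges must be non-degenerate and ordered")
    k1 = (dbp_hi - dbp_lo) / (1.0 / ptt_lo - 1.0 / ptt_hi)
    k2 = dbp_lo - k1 / ptt_hi
    return BPModelParams(a=a, b=b, k1=k1, k2=k2)
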