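"""Deterministic structural K-PD model.

Sodium nitroprusside is cleared too fast to measure in plasma, so drug
exposure is represented by the concentration of a hypothetical effect
compartment driven directly by the infusion-rate history (a K-PD model).
The compartment is a one-compartment system with a nominal volume of
1 L/70 kg; its clearance and volume scale with body weight by theory-based
allometry (exponents 0.75 and 1). Mean arterial pressure responds to the
effect-compartment concentration through an inhibitory sigmoid Emax (Hill)
function, superimposed on an age-dependent baseline and a linear drift in
MAP over time ("disease progression", reflecting e.g. lightening
anaesthesia):

    MAP(t) = S0(age) - Emax * Ce(t)^g / (EC50^g + Ce(t)^g) + alpha * t

Two latent subpopulations differ in EC50 (drug-sensitive "low" and
resistant "high"); which EC50 applies to a subject is a mixture draw
handled by :mod:`snpkpd.population`. Everything in this module is
deterministic and operates on scalar/array floats in internal units
(hours, µg, L, mm Hg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .units import REF_WEIGHT_KG, rate70_to_ug_kg_min, ug_to_mg

ALLOMETRIC_CL_EXPONENT = 0.75
ALLOMETRIC_V_EXPONENT = 1.0

__all__ = [
    "SubjectCovariates",
    "StructuralParams",
    "InfusionSchedule",
    "EffectExposure",
    "ER50",
    "scale_clearance",
    "scale_volume",
    "baseline_map",
    "effect_concentration",
    "map_at_time",
    "steady_state_er50",
    "effect_half_life",
]


@dataclass(frozen=True)
class SubjectCovariates:
    """Covariates entering the structural model.

    age
        Post-natal age in years (> 0).
    weight
        Body weight in kg (> 0).
    """

    age: float
    weight: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.age) and self.age > 0):
            raise ValueError(f"age must be a positive finite number of years, got {self.age}")
        if not (math.isfinite(self.weight) and self.weight > 0):
            raise ValueError(f"weight must be a positive finite number of kg, got {self.weight}")


@dataclass(frozen=True)
class StructuralParams:
    """Population fixed effects of the K-PD model.

    Units: ``cl_std`` L/h per 70 kg; ``v_std`` L per 70 kg (conventionally
    fixed to 1); ``s0_std`` mm Hg at the median age; ``emax`` mm Hg
    (population maximal MAP decrease); EC50s in µg/L; ``slope`` in
    mm Hg/h (any sign); ``p_high`` the mixture probability of the
    high-EC50 (drug-resistant) subpopulation.
    """

    cl_std: float
    v_std: float
    s0_std: float
    pwr_age: float
    median_age: float
    emax: float
    ec50_low: float
    ec50_high: float
    gamma: float
    slope: float
    p_high: float

    def __post_init__(self) -> None:
        positive = {
            "cl_std": self.cl_std,
            "v_std": self.v_std,
            "s0_std": self.s0_std,
            "median_age": self.median_age,
            "emax": self.emax,
            "ec50_low": self.ec50_low,
            "ec50_high": self.ec50_high,
            "gamma": self.gamma,
        }
        for name, value in positive.items():
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be positive and finite, got {value}")
        if not math.isfinite(self.slope):
            raise ValueError("slope must be finite")
        if not math.isfinite(self.pwr_age):
            raise ValueError("pwr_age must be finite")
        if not 0.0 <= self.p_high <= 1.0:
            raise ValueError(f"p_high must lie in [0, 1], got {self.p_high}")
        if not self.ec50_low < self.ec50_high:
            raise ValueError(
                f"ec50_low ({self.ec50_low}) must be strictly below ec50_high ({self.ec50_high})"
            )
        if not self.emax < self.s0_std:
            raise ValueError("emax must be below s0_std (the maximal MAP drop cannot exceed baseline)")

    def ec50(self, label: str) -> float:
        if label == "low":
            return self.ec50_low
        if label == "high":
            return self.ec50_high
        raise ValueError(f"unknown mixture label {label!r} (expected 'low' or 'high')")

    @property
    def emax_fraction(self) -> float:
        """Population maximal fractional MAP drop, emax / s0_std, in (0, 1)."""
        return self.emax / self.s0_std


class EffectExposure(NamedTuple):
    """One (time, effect-compartment concentration) sample."""

    time: float  # h
    ce: float  # µg/L


@dataclass(frozen=True)
class InfusionSchedule:
    """Piecewise-constant infusion history.

    ``segments`` is an ordered tuple of ``(start_time_h, rate_ug_per_h)``
    with strictly increasing start times; the rate is zero before the
    first segment and after ``end_time``.
    """

    segments: tuple[tuple[float, float], ...]
    end_time: float

    def __post_init__(self) -> None:
        segs = tuple((float(t), float(r)) for t, r in self.segments)
        object.__setattr__(self, "segments", segs)
        times = [t for t, _ in segs]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("segment start times must be strictly increasing")
        if any(r < 0 for _, r in segs):
            raise ValueError("infusion rates must be non-negative")
        if segs and self.end_time <= segs[-1][0]:
            raise ValueError("end_time must lie after the last segment start")

    @classmethod
    def constant(cls, rate_ug_h: float, duration_h: float, start_h: float = 0.0) -> "InfusionSchedule":
        return cls(segments=((start_h, rate_ug_h),), end_time=start_h + duration_h)

    def rate_at(self, t: float) -> float:
        if not self.segments or t < self.segments[0][0] or t >= self.end_time:
            return 0.0
        rate = 0.0
        for start, r in self.segments:
            if t >= start:
                rate = r
            else:
                break
        return rate

    def pieces(self) -> list[tuple[float, float]]:
        """Segments closed with an explicit zero-rate tail at end_time."""
        out = list(self.segments)
        out.append((self.end_time, 0.0))
        return out


def scale_clearance(weight: float, cl_std: float) -> float:
    """Allometric clearance: cl_std * (weight/70)^0.75 in L/h."""
    if not weight > 0:
        raise ValueError(f"weight must be positive, got {weight}")
    return cl_std * (weight / REF_WEIGHT_KG) ** ALLOMETRIC_CL_EXPONENT


def scale_volume(weight: float, v_std: float) -> float:
    """Linear (allometric exponent 1) volume: v_std * (weight/70) in L."""
    if not weight > 0:
        raise ValueError(f"weight must be positive, got {weight}")
    return v_std * (weight / REF_WEIGHT_KG)


def baseline_map(age: float, s0_std: float, median_age: float, pwr_age: float) -> float:
    """Age power model for baseline MAP: s0_std * (age/median_age)^pwr_age."""
    if not age > 0:
        raise ValueError(f"age must be positive, got {age}")
    return s0_std * (age / median_age) ** pwr_age


def effect_concentration(
    schedule: InfusionSchedule,
    clearance: float,
    volume: float,
    times: Sequence[float],
) -> np.ndarray:
    """Effect-compartment concentration at the requested times (µg/L).

    Closed-form superposition for piecewise-constant input: within a
    segment of constant rate R starting from concentration C0,

        Ce(t0 + tau) = C0 * exp(-ke*tau) + (R/CL) * (1 - exp(-ke*tau))

    with ke = CL/V. Ce(0) = 0 and Ce approaches R/CL monotonically during
    a constant segment.
    """
    if not clearance > 0 or not volume > 0:
        raise ValueError("clearance and volume must be positive")
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted in increasing order")

    ke = clearance / volume
    pieces = schedule.pieces() if schedule.segments else []
    ce = np.zeros_like(t)
    if not pieces:
        return ce

    # concentration at each piece boundary, by recursion
    boundary_c = [0.0]
    for (t0, r0), (t1, _) in zip(pieces, pieces[1:]):
        decay = math.exp(-ke * (t1 - t0))
        boundary_c.append(boundary_c[-1] * decay + (r0 / clearance) * (1.0 - decay))

    starts = np.array([p[0] for p in pieces])
    rates = np.array([p[1] for p in pieces])
    cs = np.array(boundary_c)
    idx = np.searchsorted(starts, t, side="right") - 1
    inside = idx >= 0
    i = np.clip(idx, 0, len(pieces) - 1)
    tau = t - starts[i]
    decay = np.exp(-ke * tau)
    ce = np.where(inside, cs[i] * decay + (rates[i] / clearance) * (1.0 - decay), 0.0)
    return ce


def _hill(ce, ec50, gamma):
    """Fractional inhibition Ce^g/(EC50^g+Ce^g), computed in log space.

    Equivalent to expit(gamma * (log Ce - log EC50)); exact at Ce = 0 and
    overflow-safe for large Hill coefficients.
    """
    ce = np.asarray(ce, dtype=float)
    with np.errstate(divide="ignore"):
        z = gamma * (np.log(ce) - np.log(ec50))
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    out[~pos] = np.exp(z[~pos]) / (1.0 + np.exp(z[~pos]))
    return out


def map_at_time(
    s0_i: float,
    emax_i: float,
    ec50_i: float,
    gamma: float,
    slope: float,
    ce: float,
    t: float,
) -> float:
    """MAP response at one time point (mm Hg).

    The drift term ``slope * t`` applies from the start of the infusion
    only (t >= 0); pre-dose baselines carry negative times and see the
    undrifted baseline.
    """
    ce_arr = np.asarray(ce, dtype=float)
    if np.any(ce_arr < 0):
        raise ValueError("effect-compartment concentration must be non-negative")
    if not ec50_i > 0 or not gamma > 0:
        raise ValueError("ec50_i and gamma must be positive")
    if emax_i < 0:
        raise ValueError("emax_i must be non-negative")
    drug = emax_i * _hill(ce_arr, ec50_i, gamma)
    value = s0_i - drug + slope * np.maximum(np.asarray(t, dtype=float), 0.0)
    return float(value) if value.ndim == 0 else value


class ER50(NamedTuple):
    """Steady-state infusion rate giving the half-maximal effect.

    Derived from EC50 * CL; held in µg/h per 70 kg with convenience
    conversions to the units the label speaks.
    """

    ug_per_h_70kg: float

    @property
    def mg_per_h_70kg(self) -> float:
        return ug_to_mg(self.ug_per_h_70kg)

    @property
    def ug_per_kg_min(self) -> float:
        return rate70_to_ug_kg_min(self.ug_per_h_70kg)


def steady_state_er50(ec50: float, cl_std: float) -> ER50:
    """ER50 = EC50 * CL (µg/h per 70 kg) — the rate whose steady-state Ce is EC50."""
    if ec50 < 0 or not cl_std > 0:
        raise ValueError("ec50 must be >= 0 and cl_std positive")
    return ER50(ec50 * cl_std)


def effect_half_life(clearance: float, volume: float) -> float:
    """Effect-compartment half-life in minutes, 60 * ln2 * V / CL."""
    if not clearance > 0 or not volume > 0:
        raise ValueError("clearance and volume must be positive")
    return 60.0 * math.log(2.0) * volume / clearance
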