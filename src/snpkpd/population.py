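"""Between-subject variability, the EC50 mixture and residual error.

Random effects are mutually independent. CL, V, S0 and EC50 carry
exponential (lognormal) random effects; the maximal effect uses a
logistic transform of the fraction Emax/S0 so that 0 < Emax_i < S0_i for
any draw; the progression slope uses a signed proportional model
slope_i = alpha * (1 + eta) so individual slopes may change sign.
Residual error on MAP is proportional (a %CV is the only magnitude the
model carries).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .kpd_core import StructuralParams, SubjectCovariates, baseline_map, scale_clearance, scale_volume

__all__ = [
    "VarianceComponents",
    "IndividualParams",
    "draw_individual",
    "emax_transform",
    "apply_residual",
]


@dataclass(frozen=True)
class VarianceComponents:
    """Random-effect standard deviations (dimensionless) and residual SD.

    The omegas act on the scale of their transform (log scale for the
    lognormal effects, logit scale for Emax, proportional scale for the
    slope); ``sigma_prop`` is the proportional residual SD as a fraction
    (0.329 means 32.9 %CV).
    """

    omega_v: float = 0.0
    omega_cl: float = 0.0
    omega_s0: float = 0.0
    omega_ec50_low: float = 0.0
    omega_ec50_high: float = 0.0
    omega_emax: float = 0.0
    omega_slope: float = 0.0
    sigma_prop: float = 0.0

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not (math.isfinite(value) and value >= 0):
                raise ValueError(f"{name} must be a non-negative finite number, got {value}")

    def omega_ec50(self, label: str) -> float:
        if label == "low":
            return self.omega_ec50_low
        if label == "high":
            return self.omega_ec50_high
        raise ValueError(f"unknown mixture label {label!r}")


@dataclass(frozen=True)
class IndividualParams:
    """Realised subject-level parameters after covariates, random effects
    and the mixture assignment."""

    cl_i: float  # L/h
    v_i: float  # L
    s0_i: float  # mm Hg
    emax_i: float  # mm Hg
    ec50_i: float  # µg/L
    slope_i: float  # mm Hg/h
    mixture_label: str  # "low" | "high"

    def __post_init__(self) -> None:
        for name in ("cl_i", "v_i", "s0_i", "ec50_i"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.emax_i < self.s0_i:
            raise ValueError("emax_i must lie strictly between 0 and s0_i")
        if self.mixture_label not in ("low", "high"):
            raise ValueError(f"mixture_label must be 'low' or 'high', got {self.mixture_label!r}")


def emax_transform(eta_emax: float, theta: StructuralParams, s0_i: float) -> float:
    """Individual maximal MAP drop, bounded in (0, s0_i).

    The random effect acts on the logit of the fractional drop, anchored
    at the population fraction emax/s0_std:

        f_i = expit(logit(emax/s0_std) + eta),   emax_i = f_i * s0_i

    At eta = 0 this returns (emax/s0_std) * s0_i, i.e. the population
    fraction applied to the individual baseline.
    """
    if not s0_i > 0:
        raise ValueError("s0_i must be positive")
    f_pop = theta.emax_fraction
    if not 0.0 < f_pop < 1.0:
        raise ValueError("emax/s0_std must lie in (0, 1) for the logistic transform")
    return float(expit(logit(f_pop) + eta_emax) * s0_i)


def draw_individual(
    cov: SubjectCovariates,
    theta: StructuralParams,
    omega: VarianceComponents,
    rng: np.random.Generator,
) -> IndividualParams:
    """Draw one subject's parameters.

    The mixture label is Bernoulli(p_high -> "high"); all etas are
    independent normals with the stated omegas. Zero omegas reproduce the
    population values exactly.
    """
    label = "high" if rng.random() < theta.p_high else "low"
    eta = {
        name: (rng.normal(0.0, om) if om > 0 else 0.0)
        for name, om in (
            ("v", omega.omega_v),
            ("cl", omega.omega_cl),
            ("s0", omega.omega_s0),
            ("ec50", omega.omega_ec50(label)),
            ("emax", omega.omega_emax),
            ("slope", omega.omega_slope),
        )
    }
    s0_i = baseline_map(cov.age, theta.s0_std, theta.median_age, theta.pwr_age) * math.exp(eta["s0"])
    return IndividualParams(
        cl_i=scale_clearance(cov.weight, theta.cl_std) * math.exp(eta["cl"]),
        v_i=scale_volume(cov.weight, theta.v_std) * math.exp(eta["v"]),
        s0_i=s0_i,
        emax_i=emax_transform(eta["emax"], theta, s0_i),
        ec50_i=theta.ec50(label) * math.exp(eta["ec50"]),
        slope_i=theta.slope * (1.0 + eta["slope"]),
        mixture_label=label,
    )


def apply_residual(
    pred,
    sigma_prop: float,
    rng: np.random.Generator,
    *,
    positive_only: bool = False,
):
    """Proportional residual error: observed = pred * (1 + eps), eps ~ N(0, sigma^2).

    With ``positive_only`` the residual is redrawn until the observation is
    positive (used by the trial generator, where a negative blood pressure
    is not a recordable value; at sigma ~ 0.33 this truncates ~0.1% of
    draws). Accepts scalars or arrays.
    """
    pred_arr = np.atleast_1d(np.asarray(pred, dtype=float))
    if np.any(pred_arr <= 0):
        raise ValueError("pred must be positive")
    if sigma_prop == 0.0:
        out = pred_arr.copy()
    else:
        out = pred_arr * (1.0 + rng.normal(0.0, sigma_prop, size=pred_arr.shape))
        if positive_only:
            for _ in range(100):
                bad = out <= 0
                if not np.any(bad):
                    break
                out[bad] = pred_arr[bad] * (1.0 + rng.normal(0.0, sigma_prop, size=int(bad.sum())))
    if np.ndim(pred) == 0:
        return float(out[0])
    return out.reshape(np.shape(pred))
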