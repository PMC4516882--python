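"""Dose-finding simulations for labelling guidance.

Two clinical questions, answered deterministically at the population
mode (eta = 0) of the chosen EC50 subpopulation:

Scenario 1 — the constant infusion rate that achieves a stated MAP
reduction (e.g. 10 or 15 mm Hg below the patient's own baseline) at a
clinically relevant horizon (5 min).

Scenario 2 — a loading rate that brings MAP to an absolute target
(e.g. 60 mm Hg) within a few minutes, followed by a lower maintenance
rate holding the target for half an hour.

Both are monotone root-finding problems in the infusion rate and are
solved by bisection on the log rate. A stochastic companion simulates
virtual patients around the query covariates and reports the spread of
achieved MAP under the deterministic recommendation.

The default parameter set for these simulations is the bootstrap-average
column of the published estimates (see :func:`snpkpd.io.default_params`);
it reproduces the published dosing tables closely, which the final-model
column does not for the sensitive subpopulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .kpd_core import (
    InfusionSchedule,
    StructuralParams,
    SubjectCovariates,
    baseline_map,
    effect_concentration,
    map_at_time,
    scale_clearance,
    scale_volume,
)
from .population import IndividualParams, VarianceComponents, draw_individual
from .units import min_to_h, ug_kg_min_to_ug_h

__all__ = [
    "DoseQuery",
    "UnattainableTargetError",
    "population_individual",
    "simulate_regimen",
    "dose_for_reduction",
    "two_stage_doses",
    "stochastic_dose_bands",
    "scenario1_table",
    "scenario2_table",
]

_LOG_RATE_LO = math.log(1e-4)  # µg/kg/min bisection bracket
_LOG_RATE_HI = math.log(100.0)


class UnattainableTargetError(ValueError):
    """The requested MAP target exceeds what the Emax model can produce;
    the message reports the attainable range."""


@dataclass(frozen=True)
class DoseQuery:
    """One dose-finding question.

    Scenario 1 uses ``reduction`` (mm Hg below the patient's baseline)
    and ``horizon`` (min); scenario 2 uses ``target_map`` (mm Hg),
    ``attain_by`` and ``maintain_for`` (min). ``include_slope`` keeps the
    disease-progression drift in the target accounting (the response
    model contains it, so the default is on).
    """

    patient: SubjectCovariates
    subpopulation: str  # "low" | "high"
    reduction: float | None = None
    horizon: float | None = None
    target_map: float | None = None
    attain_by: float | None = None
    maintain_for: float | None = None
    include_slope: bool = True

    def __post_init__(self) -> None:
        if self.subpopulation not in ("low", "high"):
            raise ValueError("subpopulation must be 'low' or 'high'")
        scen1 = self.reduction is not None
        scen2 = self.target_map is not None
        if scen1 == scen2:
            raise ValueError("specify exactly one of reduction (scenario 1) or target_map (scenario 2)")
        if scen1 and (self.reduction <= 0 or not self.horizon or self.horizon <= 0):
            raise ValueError("scenario 1 needs reduction > 0 and horizon > 0")
        if scen2 and (
            self.target_map <= 0
            or not self.attain_by
            or self.attain_by <= 0
            or not self.maintain_for
            or self.maintain_for <= 0
        ):
            raise ValueError("scenario 2 needs target_map > 0, attain_by > 0 and maintain_for > 0")


def population_individual(theta: StructuralParams, patient: SubjectCovariates, subpop: str) -> IndividualParams:
    """Subject-level parameters at the population mode (all etas zero)."""
    s0_i = baseline_map(patient.age, theta.s0_std, theta.median_age, theta.pwr_age)
    return IndividualParams(
        cl_i=scale_clearance(patient.weight, theta.cl_std),
        v_i=scale_volume(patient.weight, theta.v_std),
        s0_i=s0_i,
        emax_i=theta.emax_fraction * s0_i,
        ec50_i=theta.ec50(subpop),
        slope_i=theta.slope,
        mixture_label=subpop,
    )


def _trajectory(ind: IndividualParams, gamma: float, schedule: InfusionSchedule, times_h, include_slope=True):
    ce = effect_concentration(schedule, ind.cl_i, ind.v_i, times_h)
    slope = ind.slope_i if include_slope else 0.0
    mp = map_at_time(ind.s0_i, ind.emax_i, ind.ec50_i, gamma, slope, ce, np.asarray(times_h))
    return ce, np.asarray(mp, dtype=float)


def simulate_regimen(
    patient: SubjectCovariates,
    subpop: str,
    schedule: InfusionSchedule,
    theta: StructuralParams,
    times_min=None,
    *,
    include_slope: bool = True,
) -> pd.DataFrame:
    """Deterministic MAP trajectory under an infusion schedule.

    Returns a frame with ``time_min``, ``ce`` (µg/L) and ``map`` (mm Hg)
    at the population mode of the chosen subpopulation.
    """
    if times_min is None:
        end = schedule.end_time * 60.0
        times_min = np.arange(0.0, end + 0.25, 0.5)
    times_h = np.asarray([min_to_h(t) for t in np.atleast_1d(times_min)], dtype=float)
    ind = population_individual(theta, patient, subpop)
    ce, mp = _trajectory(ind, theta.gamma, schedule, times_h, include_slope)
    return pd.DataFrame({"time_min": np.atleast_1d(times_min), "ce": ce, "map": mp})


def _map_under_constant_rate(ind, gamma, rate_ug_kg_min, weight, t_h, include_slope):
    sched = InfusionSchedule.constant(ug_kg_min_to_ug_h(rate_ug_kg_min, weight), t_h + 1.0)
    _, mp = _trajectory(ind, gamma, sched, np.array([t_h]), include_slope)
    return float(mp[0])


def dose_for_reduction(query: DoseQuery, theta: StructuralParams) -> float:
    """Scenario 1: constant rate (µg/kg/min) achieving the stated
    baseline-relative MAP reduction at the horizon.

    The achieved reduction at a fixed horizon is strictly increasing in
    the rate, so the rate is found by bisection on the log rate to a MAP
    error below 1e-6 mm Hg.
    """
    if query.reduction is None:
        raise ValueError("dose_for_reduction needs a scenario-1 query (reduction/horizon)")
    ind = population_individual(theta, query.patient, query.subpopulation)
    t_h = min_to_h(query.horizon)
    # drug effect needed at the horizon, net of the progression drift
    needed = query.reduction + (ind.slope_i * t_h if query.include_slope else 0.0)
    if needed <= 0.0:
        return 0.0
    if needed >= ind.emax_i:
        raise UnattainableTargetError(
            f"a reduction of {query.reduction} mm Hg at {query.horizon} min is beyond the maximal "
            f"achievable drug effect of {ind.emax_i:.2f} mm Hg for this patient"
        )
    target_map = ind.s0_i - query.reduction

    def f(log_rate):
        mp = _map_under_constant_rate(
            ind, theta.gamma, math.exp(log_rate), query.patient.weight, t_h, query.include_slope
        )
        return mp - target_map

    lo, hi = _LOG_RATE_LO, _LOG_RATE_HI
    if f(lo) <= 0.0:
        return math.exp(lo)
    if f(hi) >= 0.0:
        raise UnattainableTargetError(
            f"the target reduction is not reachable within the rate bracket "
            f"(up to {math.exp(_LOG_RATE_HI):.0f} µg/kg/min)"
        )
    sol = optimize.brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)
    return math.exp(sol)


def two_stage_doses(
    query: DoseQuery, theta: StructuralParams, *, saturation: str = "error"
) -> tuple[float, float]:
    """Scenario 2: loading and maintenance rates (µg/kg/min).

    The first rate brings MAP to ``target_map`` at ``attain_by``; the
    second starts at ``attain_by`` and is chosen so MAP is back at the
    target at the end of the maintenance window. Both by bisection on the
    log rate.

    Because the progression drift raises MAP over the window, the drug
    effect required at the end of maintenance can exceed the attainable
    maximum even when the loading target is feasible; the maintenance
    problem is then saturated and has no solution. ``saturation`` chooses
    between raising (default) and returning ``nan`` for the second rate.
    """
    if query.target_map is None:
        raise ValueError("two_stage_doses needs a scenario-2 query")
    if saturation not in ("error", "nan"):
        raise ValueError("saturation must be 'error' or 'nan'")
    ind = population_individual(theta, query.patient, query.subpopulation)
    t1 = min_to_h(query.attain_by)
    t2 = t1 + min_to_h(query.maintain_for)
    wt = query.patient.weight
    include = query.include_slope

    saturated = False
    for t, when in ((t1, "attain_by"), (t2, "end of maintenance")):
        drift = ind.slope_i * t if include else 0.0
        needed = ind.s0_i + drift - query.target_map
        if needed <= 0.0:
            # target at or above the (drifted) baseline: nothing to do
            return (0.0, 0.0)
        if needed >= ind.emax_i:
            if when == "end of maintenance" and saturation == "nan":
                saturated = True
                continue
            raise UnattainableTargetError(
                f"target MAP {query.target_map} mm Hg at {when} requires a drug effect of "
                f"{needed:.2f} mm Hg, above the attainable range (0, {ind.emax_i:.2f})"
            )

    def f1(log_rate):
        return (
            _map_under_constant_rate(ind, theta.gamma, math.exp(log_rate), wt, t1, include)
            - query.target_map
        )

    if f1(_LOG_RATE_LO) <= 0.0:
        rate1 = math.exp(_LOG_RATE_LO)
    else:
        rate1 = math.exp(optimize.brentq(f1, _LOG_RATE_LO, _LOG_RATE_HI, xtol=1e-13, rtol=8.9e-16))
    if saturated:
        return rate1, float("nan")

    def f2(log_rate):
        sched = InfusionSchedule(
            segments=(
                (0.0, ug_kg_min_to_ug_h(rate1, wt)),
                (t1, ug_kg_min_to_ug_h(math.exp(log_rate), wt)),
            ),
            end_time=t2 + 1.0,
        )
        _, mp = _trajectory(ind, theta.gamma, sched, np.array([t2]), include)
        return float(mp[0]) - query.target_map

    if f2(_LOG_RATE_LO) <= 0.0:
        rate2 = math.exp(_LOG_RATE_LO)
    else:
        rate2 = math.exp(optimize.brentq(f2, _LOG_RATE_LO, _LOG_RATE_HI, xtol=1e-13, rtol=8.9e-16))
    return rate1, rate2


def stochastic_dose_bands(
    query: DoseQuery,
    theta: StructuralParams,
    omega: VarianceComponents,
    n_sims: int = 100,
    rng: np.random.Generator | None = None,
    *,
    times_min=None,
) -> pd.DataFrame:
    """Spread of achieved MAP when the deterministic recommendation is
    applied to virtual patients with between-subject variability.

    Virtual subjects share the query covariates and subpopulation but
    redraw all random effects; the frame holds the 5th/50th/95th
    percentiles of MAP over time under the recommended regimen.
    """
    if n_sims < 2:
        raise ValueError("n_sims must be at least 2")
    if rng is None:
        rng = np.random.default_rng()
    wt = query.patient.weight
    if query.reduction is not None:
        rate = dose_for_reduction(query, theta)
        sched = InfusionSchedule.constant(ug_kg_min_to_ug_h(rate, wt), min_to_h(query.horizon) + 0.5)
        end_min = query.horizon
    else:
        r1, r2 = two_stage_doses(query, theta)
        t1 = min_to_h(query.attain_by)
        sched = InfusionSchedule(
            segments=((0.0, ug_kg_min_to_ug_h(r1, wt)), (t1, ug_kg_min_to_ug_h(r2, wt))),
            end_time=t1 + min_to_h(query.maintain_for) + 0.5,
        )
        end_min = query.attain_by + query.maintain_for
    if times_min is None:
        times_min = np.arange(0.0, end_min + 0.25, 0.5)
    times_h = np.array([min_to_h(t) for t in times_min])

    fixed_label_theta = theta
    trajs = np.empty((n_sims, len(times_h)))
    for s in range(n_sims):
        # condition the mixture on the queried subpopulation; BSV on all
        # other parameters is drawn from the model
        while True:
            ind = draw_individual(query.patient, fixed_label_theta, omega, rng)
            if ind.mixture_label == query.subpopulation:
                break
        _, mp = _trajectory(ind, theta.gamma, sched, times_h, query.include_slope)
        trajs[s] = mp
    q = np.percentile(trajs, [5, 50, 95], axis=0)
    return pd.DataFrame(
        {"time_min": times_min, "map_p5": q[0], "map_p50": q[1], "map_p95": q[2]}
    )


_REFERENCE_PATIENTS = (
    SubjectCovariates(age=0.035, weight=3.615),
    SubjectCovariates(age=0.58, weight=7.955),
    SubjectCovariates(age=4.545, weight=16.15),
    SubjectCovariates(age=10.93, weight=34.2),
    SubjectCovariates(age=14.8, weight=52.6),
)


def scenario1_table(
    theta: StructuralParams,
    reductions=(10.0, 15.0),
    horizon: float = 5.0,
    patients=_REFERENCE_PATIENTS,
    include_slope: bool = True,
) -> pd.DataFrame:
    """Single-infusion dosing table across the age-strata reference patients."""
    rows = []
    for red in reductions:
        for p in patients:
            row = {
                "age_y": p.age,
                "weight_kg": p.weight,
                "baseline_map": baseline_map(p.age, theta.s0_std, theta.median_age, theta.pwr_age),
                "reduction_mmhg": red,
            }
            for sub in ("low", "high"):
                q = DoseQuery(p, sub, reduction=red, horizon=horizon, include_slope=include_slope)
                row[f"rate_{sub}_ug_kg_min"] = dose_for_reduction(q, theta)
            rows.append(row)
    return pd.DataFrame(rows)


def scenario2_table(
    theta: StructuralParams,
    target_map: float = 60.0,
    attain_by: float = 3.0,
    maintain_for: float = 30.0,
    patients=_REFERENCE_PATIENTS,
    include_slope: bool = True,
) -> pd.DataFrame:
    """Two-stage (load + maintain) dosing table across the reference patients.

    Patients whose end-of-window drug-effect requirement saturates the
    Emax model get ``nan`` in the maintenance column (see
    :func:`two_stage_doses`).
    """
    rows = []
    for p in patients:
        row = {
            "age_y": p.age,
            "weight_kg": p.weight,
            "baseline_map": baseline_map(p.age, theta.s0_std, theta.median_age, theta.pwr_age),
            "target_map": target_map,
        }
        for sub in ("low", "high"):
            q = DoseQuery(
                p, sub, target_map=target_map, attain_by=attain_by, maintain_for=maintain_for,
                include_slope=include_slope,
            )
            r1, r2 = two_stage_doses(q, theta, saturation="nan")
            row[f"rate1_{sub}_ug_kg_min"] = r1
            row[f"rate2_{sub}_ug_kg_min"] = r2
        rows.append(row)
    return pd.DataFrame(rows)
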