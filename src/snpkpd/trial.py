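"""Synthetic blinded-phase trial generator and the NONMEM-style dataset I/O.

Emulates the dose-ranging phase of the paediatric deliberate-hypotension
trial the model was built for: four parallel arms at 0.3/1.0/2.0/3.0
µg/kg/min infused for up to 30 min, MAP sampled every 2 min plus a
pre-dose baseline window, five enrolment age strata from neonates to
adolescents, and a safety down-titration (rate halved on a first
low-MAP reading, stopped on a second). Covariate generators are a
pragmatic stand-in for the real demographics: ages are log-uniform
within each stratum and weights conditionally log-normal around
growth-curve medians anchored at the strata's published median
age/weight pairs.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .kpd_core import StructuralParams, SubjectCovariates, map_at_time
from .population import VarianceComponents, apply_residual, draw_individual
from .units import min_to_h, ug_kg_min_to_ug_h

__all__ = [
    "AgeStratum",
    "TrialDesign",
    "EventRecord",
    "DEFAULT_DESIGN",
    "sample_cohort",
    "simulate_trial",
    "write_dataset",
    "read_dataset",
    "DatasetError",
]

NEONATE_AGE_Y = 30.0 / 365.25

# (median age, median weight) anchors for the five enrolment strata, used
# as the centre of the conditional weight distribution.
_GROWTH_AGE = np.array([0.0027, 0.035, 0.58, 4.545, 10.93, 14.8, 17.0])
_GROWTH_WT = np.array([3.3, 3.615, 7.955, 16.15, 34.2, 52.6, 60.0])


@dataclass(frozen=True)
class AgeStratum:
    age_lo: float  # years, inclusive
    age_hi: float  # years, exclusive
    proportion: float

    def __post_init__(self) -> None:
        if not 0 < self.age_lo < self.age_hi:
            raise ValueError("stratum age range must satisfy 0 < lo < hi")
        if not 0 < self.proportion <= 1:
            raise ValueError("stratum proportion must lie in (0, 1]")


# Enrolment strata: birth-<30 d, 30 d-<2 y, 2-<6 y, 6 y-Tanner III
# (~12 y proxy), Tanner III-<17 y, with the trial's enrolment fractions.
DEFAULT_STRATA: tuple[AgeStratum, ...] = (
    AgeStratum(1.0 / 365.25, NEONATE_AGE_Y, 0.02),
    AgeStratum(NEONATE_AGE_Y, 2.0, 0.25),
    AgeStratum(2.0, 6.0, 0.06),
    AgeStratum(6.0, 12.0, 0.21),
    AgeStratum(12.0, 17.0, 0.46),
)


@dataclass(frozen=True)
class TrialDesign:
    """Blinded-phase design: arms, sampling schedule, cohort make-up and
    the safety down-titration rule."""

    arms: tuple[float, ...] = (0.3, 1.0, 2.0, 3.0)  # µg/kg/min
    infusion_duration: float = 30.0  # min
    baseline_window: float = 6.0  # min
    obs_interval: float = 2.0  # min
    n_subjects: int = 202
    strata: tuple[AgeStratum, ...] = DEFAULT_STRATA
    map_floor: float = 50.0  # mm Hg
    map_floor_neonate: float = 40.0  # mm Hg, age < 30 days
    weight_range: tuple[float, float] = (2.8, 112.2)  # kg
    weight_log_sd: float = 0.18

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.arms):
            raise ValueError("arm infusion rates must be positive")
        if self.obs_interval <= 0 or self.infusion_duration <= 0 or self.baseline_window < 0:
            raise ValueError("schedule durations must be positive")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        if not self.strata:
            raise ValueError("at least one covariate stratum is required")
        total = sum(s.proportion for s in self.strata)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stratum proportions must sum to 1, got {total}")

    def floor_for(self, age: float) -> float:
        return self.map_floor_neonate if age < NEONATE_AGE_Y else self.map_floor

    def baseline_times(self) -> np.ndarray:
        """Minutes, from -baseline_window up to and including 0 (pre-dose)."""
        return np.arange(-self.baseline_window, 0.5 * self.obs_interval, self.obs_interval)

    def on_treatment_times(self) -> np.ndarray:
        return np.arange(self.obs_interval, self.infusion_duration + 0.5 * self.obs_interval, self.obs_interval)


DEFAULT_DESIGN = TrialDesign()


@dataclass(frozen=True)
class EventRecord:
    """One row of the longitudinal dataset (dose event or MAP observation).

    Times are minutes relative to the start of the blinded infusion;
    baseline observations carry times in [-baseline_window, 0]. Dose rows
    hold a rate in µg/kg/min and no observation; observation rows the
    reverse.
    """

    subject_id: int
    time: float  # min
    event_type: str  # dose_start | dose_change | dose_stop | observation
    rate: float | None
    map_obs: float | None
    weight: float
    age: float
    arm: float
    mixture_label: str | None = None

    def __post_init__(self) -> None:
        if self.event_type == "observation":
            if self.map_obs is None or self.map_obs <= 0:
                raise ValueError("observation rows need a positive map_obs")
            if self.rate is not None:
                raise ValueError("observation rows must not carry a rate")
        elif self.event_type in ("dose_start", "dose_change", "dose_stop"):
            if self.rate is None or self.rate < 0:
                raise ValueError("dose rows need a non-negative rate")
            if self.map_obs is not None:
                raise ValueError("dose rows must not carry map_obs")
            if self.time < 0:
                raise ValueError("dose events cannot precede the infusion start")
        else:
            raise ValueError(f"unknown event_type {self.event_type!r}")

    @property
    def is_observation(self) -> bool:
        return self.event_type == "observation"


def _sample_stratum_covariates(stratum: AgeStratum, design: TrialDesign, rng: np.random.Generator) -> SubjectCovariates:
    log_age = rng.uniform(math.log(stratum.age_lo), math.log(stratum.age_hi))
    age = math.exp(log_age)
    median_wt = float(np.interp(math.log(age), np.log(_GROWTH_AGE), np.log(_GROWTH_WT)))
    wt = math.exp(median_wt + rng.normal(0.0, design.weight_log_sd))
    lo, hi = design.weight_range
    wt = min(max(wt, lo, 2.5), hi)
    return SubjectCovariates(age=age, weight=wt)


def sample_cohort(design: TrialDesign, rng: np.random.Generator) -> list[SubjectCovariates]:
    """Draw the study cohort: stratum by enrolment proportion, log-uniform
    age within stratum, conditional log-normal weight clipped to the
    enrolled range (and >= 2.5 kg for neonates)."""
    props = np.array([s.proportion for s in design.strata])
    idx = rng.choice(len(design.strata), size=design.n_subjects, p=props)
    return [_sample_stratum_covariates(design.strata[i], design, rng) for i in idx]


def simulate_trial(
    design: TrialDesign,
    theta: StructuralParams,
    omega: VarianceComponents,
    rng: np.random.Generator,
    *,
    keep_mixture: bool = True,
) -> list[EventRecord]:
    """Simulate one blinded-phase dataset.

    Each subject is randomised to an arm with equal probability, observed
    over the pre-dose window and every ``obs_interval`` minutes on
    treatment; a noisy MAP below the age-dependent floor halves the rate
    (first violation) and stops the infusion (second violation). The
    mixture truth is carried in the records when ``keep_mixture``.
    """
    records: list[EventRecord] = []
    cohort = sample_cohort(design, rng)
    arms_idx = rng.integers(0, len(design.arms), size=design.n_subjects)
    for sid, (cov, ai) in enumerate(zip(cohort, arms_idx), start=1):
        arm = design.arms[int(ai)]
        ind = draw_individual(cov, theta, omega, rng)
        label = ind.mixture_label if keep_mixture else None
        base = dict(subject_id=sid, weight=cov.weight, age=cov.age, arm=arm, mixture_label=label)

        for t in design.baseline_times():
            obs = apply_residual(ind.s0_i, omega.sigma_prop, rng, positive_only=True)
            records.append(EventRecord(time=float(t), event_type="observation", rate=None, map_obs=obs, **base))

        records.append(EventRecord(time=0.0, event_type="dose_start", rate=arm, map_obs=None, **base))

        ke = ind.cl_i / ind.v_i
        floor = design.floor_for(cov.age)
        rate = arm
        ce = 0.0
        t_last = 0.0
        violations = 0
        for t in design.on_treatment_times():
            tau = min_to_h(float(t) - t_last)
            rate_abs = ug_kg_min_to_ug_h(rate, cov.weight)
            decay = math.exp(-ke * tau)
            ce = ce * decay + (rate_abs / ind.cl_i) * (1.0 - decay)
            t_last = float(t)
            pred = map_at_time(
                ind.s0_i, ind.emax_i, ind.ec50_i, theta.gamma, ind.slope_i, ce, min_to_h(float(t))
            )
            pred = max(pred, 1e-3)  # pathological draws cannot yield a non-positive pressure
            obs = apply_residual(pred, omega.sigma_prop, rng, positive_only=True)
            records.append(EventRecord(time=float(t), event_type="observation", rate=None, map_obs=obs, **base))
            if obs < floor and rate > 0 and float(t) < design.infusion_duration:
                violations += 1
                rate = rate / 2.0 if violations == 1 else 0.0
                etype = "dose_change" if violations == 1 else "dose_stop"
                records.append(EventRecord(time=float(t), event_type=etype, rate=rate, map_obs=None, **base))
        if rate > 0:
            records.append(
                EventRecord(time=design.infusion_duration, event_type="dose_stop", rate=0.0, map_obs=None, **base)
            )
    return records


# ---------------------------------------------------------------------------
# dataset I/O — NONMEM-convention CSV

_COLUMNS = ["ID", "TIME", "AMT", "RATE", "DV", "EVID", "MDV", "WT", "AGE", "ARM", "MIXTURE"]


class DatasetError(ValueError):
    """Malformed dataset file; the message names the offending line."""


def _fmt(x, ndigits):
    return "." if x is None else f"{round(float(x), ndigits):g}"


def write_dataset(records: Iterable[EventRecord], path: str | Path) -> None:
    """Write records as CSV with NONMEM-style columns.

    Missing numeric fields are encoded as ".". MAP is stored to 0.1 mm Hg
    and rates to 0.001 µg/kg/min, so the read/write round trip is exact at
    storage precision.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_COLUMNS)
        for r in records:
            evid = 0 if r.is_observation else 1
            w.writerow(
                [
                    r.subject_id,
                    f"{r.time:g}",
                    ".",
                    _fmt(r.rate, 3),
                    _fmt(r.map_obs, 1),
                    evid,
                    evid,  # MDV mirrors EVID here: doses have no DV
                    f"{r.weight:g}",
                    f"{r.age:g}",
                    f"{r.arm:g}",
                    r.mixture_label if r.mixture_label is not None else ".",
                ]
            )


def read_dataset(path: str | Path) -> list[EventRecord]:
    """Read a dataset CSV back into records, enforcing row invariants.

    The dose event type is reconstructed from the rate sequence: the first
    dose row of a subject is a start, a zero-rate row a stop, anything
    else a change.
    """
    path = Path(path)
    records: list[EventRecord] = []
    seen_dose: set[int] = set()
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _COLUMNS:
            raise DatasetError(f"{path}: line 1: expected header {','.join(_COLUMNS)}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(_COLUMNS):
                raise DatasetError(f"{path}: line {lineno}: expected {len(_COLUMNS)} fields, got {len(row)}")
            try:
                sid = int(row[0])
                time = float(row[1])
                rate = None if row[3].strip() == "." else float(row[3])
                dv = None if row[4].strip() == "." else float(row[4])
                evid = int(row[5])
                wt = float(row[7])
                age = float(row[8])
                arm = float(row[9])
                mix = None if row[10].strip() == "." else row[10].strip()
            except ValueError as exc:
                raise DatasetError(f"{path}: line {lineno}: {exc}") from exc
            try:
                if evid == 0:
                    if rate is not None:
                        raise ValueError("observation row carries a rate")
                    rec = EventRecord(sid, time, "observation", None, dv, wt, age, arm, mix)
                elif evid == 1:
                    if dv is not None:
                        raise ValueError("dose row carries a DV")
                    if rate is None:
                        raise ValueError("dose row missing RATE")
                    if sid not in seen_dose:
                        etype = "dose_start"
                        seen_dose.add(sid)
                    else:
                        etype = "dose_stop" if rate == 0 else "dose_change"
                    rec = EventRecord(sid, time, etype, rate, dv, wt, age, arm, mix)
                else:
                    raise ValueError(f"unsupported EVID {evid}")
            except ValueError as exc:
                raise DatasetError(f"{path}: line {lineno}: {exc}") from exc
            records.append(rec)
    return records
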