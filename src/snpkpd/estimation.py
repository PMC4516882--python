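"""Maximum-likelihood estimation of the population K-PD model.

The marginal likelihood integrates the subject-level random effects out
of the conditional likelihood; the integral is approximated by Laplace's
method at the per-subject posterior mode (a mode-plus-curvature stand-in
for NONMEM's FOCE family). The two EC50 subpopulations enter as a
two-component mixture at the subject level, so the objective function is

    OFV = -2 * sum_i log[ p * L_i(high) + (1 - p) * L_i(low) ]

maximised over transformed parameters: logs for positive quantities,
logits for the mixture probability and the Emax fraction, and
ec50_high = ec50_low * (1 + delta) with delta > 0 so the component labels
cannot switch during optimisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from ._batch import SubjectBatch, laplace_multimodal, mixture_loglik
from .kpd_core import StructuralParams
from .population import VarianceComponents

__all__ = [
    "FitResult",
    "BootstrapResult",
    "DEFAULT_FIXED",
    "subject_marginal_likelihood",
    "total_ofv",
    "fit_model",
    "empirical_bayes",
    "bootstrap_fit",
    "likelihood_ratio_test",
]

# v_std is conventionally not estimable from dose-response data alone and
# is fixed to its nominal 1 L/70 kg unless explicitly freed.
DEFAULT_FIXED = frozenset({"v_std"})

_THETA_NAMES = (
    "cl_std",
    "v_std",
    "s0_std",
    "pwr_age",
    "emax_frac",
    "ec50_low",
    "ec50_delta",
    "gamma",
    "slope",
    "p_high",
)
_OMEGA_NAMES = (
    "omega_v",
    "omega_cl",
    "omega_s0",
    "omega_ec50_low",
    "omega_ec50_high",
    "omega_emax",
    "omega_slope",
    "sigma_prop",
)
PARAM_NAMES = _THETA_NAMES + _OMEGA_NAMES
_LOG_PARAMS = frozenset(
    {"cl_std", "v_std", "s0_std", "ec50_low", "ec50_delta", "gamma"} | set(_OMEGA_NAMES)
)
_LOGIT_PARAMS = frozenset({"emax_frac", "p_high"})


def _params_to_dict(theta: StructuralParams, omega: VarianceComponents) -> dict[str, float]:
    d = {
        "cl_std": theta.cl_std,
        "v_std": theta.v_std,
        "s0_std": theta.s0_std,
        "pwr_age": theta.pwr_age,
        "emax_frac": theta.emax_fraction,
        "ec50_low": theta.ec50_low,
        "ec50_delta": theta.ec50_high / theta.ec50_low - 1.0,
        "gamma": theta.gamma,
        "slope": theta.slope,
        "p_high": theta.p_high,
    }
    for name in _OMEGA_NAMES:
        d[name] = getattr(omega, name)
    return d


def _dict_to_params(d: dict[str, float], median_age: float) -> tuple[StructuralParams, VarianceComponents]:
    theta = StructuralParams(
        cl_std=d["cl_std"],
        v_std=d["v_std"],
        s0_std=d["s0_std"],
        pwr_age=d["pwr_age"],
        median_age=median_age,
        emax=d["emax_frac"] * d["s0_std"],
        ec50_low=d["ec50_low"],
        ec50_high=d["ec50_low"] * (1.0 + d["ec50_delta"]),
        gamma=d["gamma"],
        slope=d["slope"],
        p_high=d["p_high"],
    )
    omega = VarianceComponents(**{name: d[name] for name in _OMEGA_NAMES})
    return theta, omega


def _transform(name: str, value: float) -> float:
    if name in _LOG_PARAMS:
        if value <= 0:
            raise ValueError(f"cannot estimate {name} from a non-positive initial value {value}")
        return math.log(value)
    if name in _LOGIT_PARAMS:
        if not 0.0 < value < 1.0:
            raise ValueError(f"cannot estimate {name} from initial value {value} outside (0, 1)")
        return float(logit(value))
    return float(value)


def _back_transform(name: str, x: float) -> float:
    if name in _LOG_PARAMS:
        return math.exp(x)
    if name in _LOGIT_PARAMS:
        return float(expit(x))
    return float(x)


@dataclass
class FitResult:
    """Estimates, objective value and per-subject empirical Bayes output."""

    theta_hat: StructuralParams
    omega_hat: VarianceComponents
    ofv: float
    converged: bool
    n_subjects: int
    n_obs: int
    fixed: frozenset[str]
    message: str = ""
    n_iter: int = 0
    se: dict[str, float] | None = None
    ebe: pd.DataFrame | None = None


def _as_batch(dataset) -> SubjectBatch:
    if isinstance(dataset, SubjectBatch):
        return dataset
    return SubjectBatch.from_records(dataset)


def subject_marginal_likelihood(
    subject_records,
    theta: StructuralParams,
    omega: VarianceComponents,
    component: str,
) -> float:
    """Laplace log marginal likelihood of one subject for one mixture component."""
    batch = _as_batch(subject_records)
    if batch.n != 1:
        raise ValueError("subject_records must contain exactly one subject")
    res, _ = laplace_multimodal(batch, theta, omega, component, multistart=True)
    return float(res.loglik[0])


def total_ofv(
    dataset,
    theta: StructuralParams,
    omega: VarianceComponents,
    cache: dict | None = None,
    *,
    multistart: bool = False,
) -> float:
    """-2 log marginal mixture likelihood of the whole dataset."""
    batch = _as_batch(dataset)
    if batch.n == 0:
        raise ValueError("dataset contains no subjects")
    total, _, _ = mixture_loglik(batch, theta, omega, cache, multistart=multistart)
    return float(-2.0 * np.sum(total))


def fit_model(
    dataset,
    init_theta: StructuralParams,
    init_omega: VarianceComponents,
    *,
    fixed: frozenset[str] | set[str] = DEFAULT_FIXED,
    maxiter: int = 100,
    maxfun: int = 120,
    ftol: float = 1e-6,
    compute_ebe: bool = True,
    verbose: bool = False,
) -> FitResult:
    """Fit by minimising the OFV over transformed free parameters.

    ``fixed`` names parameters (see ``PARAM_NAMES``; Emax is fitted as the
    fraction ``emax_frac`` = emax/s0_std and the high EC50 as the
    positive offset ``ec50_delta``) held at their initial values. Omegas
    fixed at zero drop the corresponding random effect from the model.
    Warm starts for the inner per-subject modes are carried across outer
    iterations. Non-convergence returns the best point found, flagged.
    """
    batch = _as_batch(dataset)
    fixed = frozenset(fixed)
    unknown = fixed - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter names in fixed: {sorted(unknown)}")
    full0 = _params_to_dict(init_theta, init_omega)
    free = [n for n in PARAM_NAMES if n not in fixed]
    x0 = np.array([_transform(n, full0[n]) for n in free])

    cache: dict = {}
    n_eval = [0]

    def unpack(x: np.ndarray):
        d = dict(full0)
        for name, xi in zip(free, x):
            d[name] = _back_transform(name, float(xi))
        return _dict_to_params(d, init_theta.median_age)

    def objective(x: np.ndarray, local_cache: dict, multistart: bool = False) -> float:
        theta, omega = unpack(x)
        n_eval[0] += 1
        return total_ofv(batch, theta, omega, local_cache, multistart=multistart)

    def _copy_cache(c: dict) -> dict:
        return {k: (rows.copy(), eta.copy()) for k, (rows, eta) in c.items()}

    eps = 1e-4  # forward-difference step on the transformed scale
    refresh_every = 5  # centre evals between inner multi-start refreshes
    n_center = [0]

    best = {"f": np.inf, "cache": cache}

    def value_and_grad(x: np.ndarray):
        # Every evaluation seeds the inner optimiser from the per-subject
        # modes of the best point seen so far (so a wild line-search
        # excursion cannot poison later evaluations), and each finite
        # difference seeds from the centre's modes, so the difference
        # compares modes from the same posterior basin and the gradient
        # stays clean even though the marginal likelihood is itself found
        # by optimisation.
        center = _copy_cache(best["cache"])
        ms = n_center[0] % refresh_every == 0
        n_center[0] += 1
        f0 = objective(x, center, multistart=ms)
        if f0 < best["f"]:
            best["f"] = f0
            best["cache"] = _copy_cache(center)
        g = np.empty_like(x)
        for j in range(len(x)):
            xj = x.copy()
            xj[j] += eps
            local = _copy_cache(center)
            g[j] = (objective(xj, local) - f0) / eps
        if verbose:
            print(f"  eval {n_eval[0]}: OFV = {f0:.3f}")
        return f0, g

    bounds = [(-20.0, 20.0) if n not in ("slope", "pwr_age") else (-1e3, 1e3) for n in free]
    res = optimize.minimize(
        value_and_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "maxfun": maxfun, "ftol": ftol * 1e-3, "gtol": 5e-3, "maxcor": 25},
    )
    theta_hat, omega_hat = unpack(res.x)
    fit = FitResult(
        theta_hat=theta_hat,
        omega_hat=omega_hat,
        ofv=float(res.fun),
        # scipy status 2 is line-search exhaustion: no further descent found
        # at finite-difference resolution, i.e. the practical optimum
        converged=bool(res.success or res.status == 2),
        n_subjects=batch.n,
        n_obs=batch.n_obs_total,
        fixed=fixed,
        message=str(res.message),
        n_iter=int(res.nit),
    )
    if compute_ebe:
        fit.ebe = empirical_bayes(batch, theta_hat, omega_hat)
    return fit


def empirical_bayes(dataset, theta: StructuralParams, omega: VarianceComponents) -> pd.DataFrame:
    """Per-subject posterior modes and mixture responsibilities.

    The responsibility of the high-EC50 component is

        r_i = p * L_i(high) / (p * L_i(high) + (1 - p) * L_i(low))

    and subjects are assigned to the argmax component for diagnostics.
    Columns ``eta_*_low`` / ``eta_*_high`` hold the component-conditional
    random-effect modes.
    """
    batch = _as_batch(dataset)
    _, res_low, res_high = mixture_loglik(batch, theta, omega)
    p = theta.p_high
    if p <= 0.0:
        r_high = np.zeros(batch.n)
    elif p >= 1.0:
        r_high = np.ones(batch.n)
    else:
        log_h = math.log(p) + res_high.loglik
        log_l = math.log1p(-p) + res_low.loglik
        r_high = np.exp(log_h - np.logaddexp(log_h, log_l))
    out = pd.DataFrame(
        {
            "subject_id": batch.ids,
            "loglik_low": res_low.loglik,
            "loglik_high": res_high.loglik,
            "resp_high": r_high,
            "label": np.where(r_high >= 0.5, "high", "low"),
        }
    )
    from ._batch import ETA_DIMS

    for j, dim in enumerate(ETA_DIMS):
        out[f"eta_{dim}_low"] = res_low.eta_full[:, j]
        out[f"eta_{dim}_high"] = res_high.eta_full[:, j]
    return out


@dataclass
class BootstrapResult:
    """Non-parametric bootstrap summary: one row per parameter."""

    table: pd.DataFrame  # index: parameter; columns: estimate, mean, rse_pct, ci_lo, ci_hi
    n_requested: int
    n_converged: int
    estimates: pd.DataFrame  # per-replicate parameter values


def bootstrap_fit(
    dataset,
    n_reps: int,
    rng: np.random.Generator,
    *,
    init_theta: StructuralParams | None = None,
    init_omega: VarianceComponents | None = None,
    base_fit: FitResult | None = None,
    fixed: frozenset[str] | set[str] = DEFAULT_FIXED,
    maxiter: int = 200,
    resampler=None,
) -> BootstrapResult:
    """Resample subjects with replacement and refit each replicate.

    Each refit is warm-started from the original estimates. Replicates
    whose optimiser does not converge are dropped and counted. The
    summary reports, per parameter, the point estimate, the bootstrap
    mean, %RSE (100 * SD / |mean|) and the 2.5/97.5 percentile interval.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    batch = _as_batch(dataset)
    if base_fit is None:
        if init_theta is None or init_omega is None:
            raise ValueError("provide either base_fit or init_theta and init_omega")
        base_fit = fit_model(batch, init_theta, init_omega, fixed=fixed, maxiter=maxiter, compute_ebe=False)
    theta0, omega0 = base_fit.theta_hat, base_fit.omega_hat

    rows = []
    n_conv = 0
    for rep in range(n_reps):
        if resampler is not None:
            take = np.asarray(resampler(batch.n, rep), dtype=int)
        else:
            take = rng.integers(0, batch.n, size=batch.n)
        sub = batch.subset(take)
        fit = fit_model(sub, theta0, omega0, fixed=base_fit.fixed, maxiter=maxiter, compute_ebe=False)
        if not fit.converged:
            continue
        n_conv += 1
        rows.append(_params_to_dict(fit.theta_hat, fit.omega_hat))
    est = pd.DataFrame(rows)
    point = _params_to_dict(theta0, omega0)
    summary_rows = {}
    for name in PARAM_NAMES:
        if est.empty:
            summary_rows[name] = (point[name], np.nan, np.nan, np.nan, np.nan)
            continue
        vals = est[name].to_numpy()
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rse = 100.0 * sd / abs(mean) if mean != 0 else np.nan
        lo, hi = (np.percentile(vals, [2.5, 97.5]) if len(vals) > 1 else (mean, mean))
        summary_rows[name] = (point[name], mean, rse, float(lo), float(hi))
    table = pd.DataFrame.from_dict(
        summary_rows, orient="index", columns=["estimate", "mean", "rse_pct", "ci_lo", "ci_hi"]
    )
    return BootstrapResult(table=table, n_requested=n_reps, n_converged=n_conv, estimates=est)


def likelihood_ratio_test(ofv_reduced: float, ofv_full: float, df: int, *, tol: float = 1e-6) -> float:
    """P-value of the chi-square likelihood-ratio test on an OFV difference."""
    if df < 1:
        raise ValueError("df must be at least 1")
    delta = ofv_reduced - ofv_full
    if delta < -tol:
        raise ValueError(
            f"reduced-model OFV ({ofv_reduced}) is below the full-model OFV ({ofv_full}); "
            "the models are not nested or the fits did not converge"
        )
    return float(stats.chi2.sf(max(delta, 0.0), df))
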