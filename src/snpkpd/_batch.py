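"""Vectorised cohort machinery shared by estimation and the VPC.

The marginal likelihood of a nonlinear mixed-effects model needs, for
every subject and every mixture component, an inner optimisation over the
subject's random effects. Doing that subject-by-subject in Python is too
slow for desk-scale refits, so this module lays the whole cohort out in
rectangular arrays (observations and dose segments padded to a common
width) and runs the structural model, the conditional log-likelihood and
a damped-Newton inner optimiser over all subjects at once. Gradients and
Hessians of the joint log-density are central finite differences on the
eta scale, evaluated for the full cohort in a single batched call.

Random effects live in a fixed canonical order ``ETA_DIMS``; components
with zero variance are simply excluded from the inner problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kpd_core import StructuralParams
from .population import VarianceComponents
from .units import REF_WEIGHT_KG, min_to_h, ug_kg_min_to_ug_h

ETA_DIMS = ("v", "cl", "s0", "ec50", "emax", "slope")
_IV, _ICL, _IS0, _IEC, _IEM, _ISL = range(6)
LOG2PI = math.log(2.0 * math.pi)
_PRED_FLOOR = 0.1  # mm Hg; conditional density floor, with quadratic penalty below


@dataclass
class SubjectBatch:
    """Cohort as rectangular arrays (internal units: hours, µg, µg/h)."""

    ids: np.ndarray  # (n,) original subject ids
    age: np.ndarray  # (n,) years
    wt: np.ndarray  # (n,) kg
    t_obs: np.ndarray  # (n, T) h, 0-padded
    y: np.ndarray  # (n, T) mm Hg, 1-padded
    mask: np.ndarray  # (n, T) bool, True where a real observation
    seg_t: np.ndarray  # (n, S) segment start times, h; padded with +1e6
    seg_r: np.ndarray  # (n, S) segment rates, µg/h; padded 0
    obs_seg: np.ndarray  # (n, T) segment index of each observation, -1 pre-dose
    mixture: list  # (n,) recorded truth labels or None

    @property
    def n(self) -> int:
        return self.ids.shape[0]

    @property
    def n_obs_total(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def from_records(cls, records) -> "SubjectBatch":
        order: list[int] = []
        per: dict[int, dict] = {}
        for r in records:
            if r.subject_id not in per:
                order.append(r.subject_id)
                per[r.subject_id] = {"obs": [], "dose": [], "age": r.age, "wt": r.weight, "mix": r.mixture_label}
            d = per[r.subject_id]
            if r.is_observation:
                d["obs"].append((min_to_h(r.time), r.map_obs))
            else:
                d["dose"].append((min_to_h(r.time), ug_kg_min_to_ug_h(r.rate, r.weight)))
        n = len(order)
        T = max(len(per[i]["obs"]) for i in order)
        S = max(max((len(per[i]["dose"]) for i in order), default=1), 1)
        t_obs = np.zeros((n, T))
        y = np.ones((n, T))
        mask = np.zeros((n, T), dtype=bool)
        seg_t = np.full((n, S), 1e6)
        seg_r = np.zeros((n, S))
        obs_seg = np.full((n, T), -1, dtype=int)
        age = np.empty(n)
        wt = np.empty(n)
        mixture = []
        for i, sid in enumerate(order):
            d = per[sid]
            age[i], wt[i] = d["age"], d["wt"]
            mixture.append(d["mix"])
            obs = sorted(d["obs"])
            if not obs:
                raise ValueError(f"subject {sid} has no observations")
            k = len(obs)
            t_obs[i, :k] = [t for t, _ in obs]
            y[i, :k] = [v for _, v in obs]
            mask[i, :k] = True
            dose = sorted(d["dose"])
            for j, (t, r) in enumerate(dose):
                seg_t[i, j], seg_r[i, j] = t, r
            if dose:
                starts = np.array([t for t, _ in dose])
                obs_seg[i, :k] = np.searchsorted(starts, t_obs[i, :k], side="right") - 1
        return cls(
            ids=np.array(order),
            age=age,
            wt=wt,
            t_obs=t_obs,
            y=y,
            mask=mask,
            seg_t=seg_t,
            seg_r=seg_r,
            obs_seg=obs_seg,
            mixture=mixture,
        )

    def subset(self, rows: np.ndarray) -> "SubjectBatch":
        """Row-select subjects (used by the bootstrap; rows may repeat)."""
        return SubjectBatch(
            ids=np.arange(1, len(rows) + 1),
            age=self.age[rows],
            wt=self.wt[rows],
            t_obs=self.t_obs[rows],
            y=self.y[rows],
            mask=self.mask[rows],
            seg_t=self.seg_t[rows],
            seg_r=self.seg_r[rows],
            obs_seg=self.obs_seg[rows],
            mixture=[self.mixture[i] for i in rows],
        )


def _expit(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def effect_conc(batch: SubjectBatch, cl, v):
    """Effect-compartment concentration at every observation, batched.

    ``cl`` and ``v`` have shape (..., n); returns (..., n, T). Closed-form
    recursion over segment boundaries followed by within-segment decay.
    """
    ke = cl / v
    S = batch.seg_t.shape[1]
    C = np.zeros(np.shape(cl))
    bounds = [C]
    for k in range(S - 1):
        dt = batch.seg_t[:, k + 1] - batch.seg_t[:, k]
        decay = np.exp(-ke * np.minimum(dt, 1e3))
        C = C * decay + (batch.seg_r[:, k] / cl) * (1.0 - decay)
        bounds.append(C)
    CB = np.stack(np.broadcast_arrays(*bounds), axis=-1)  # (..., n, S)

    idx = np.clip(batch.obs_seg, 0, S - 1)  # (n, T)
    idx_b = np.broadcast_to(idx, np.shape(cl) + (batch.t_obs.shape[1],))
    C0 = np.take_along_axis(CB, idx_b, axis=-1)
    r0 = np.take_along_axis(batch.seg_r, idx, axis=-1)  # (n, T)
    t0 = np.take_along_axis(batch.seg_t, idx, axis=-1)
    tau = np.maximum(batch.t_obs - t0, 0.0)
    decay = np.exp(-ke[..., None] * tau)
    ce = C0 * decay + (r0 / cl[..., None]) * (1.0 - decay)
    return np.where(batch.obs_seg >= 0, np.maximum(ce, 0.0), 0.0)


def predict_map(batch: SubjectBatch, theta: StructuralParams, eta_full, ec50):
    """MAP prediction for every observation.

    ``eta_full`` has shape (..., n, 6) in ``ETA_DIMS`` order; ``ec50`` is
    the component nominal EC50, scalar or (..., n). Returns (..., n, T).
    """
    eta_full = np.asarray(eta_full, dtype=float)
    w70 = batch.wt / REF_WEIGHT_KG
    cl = theta.cl_std * w70 ** 0.75 * np.exp(eta_full[..., _ICL])
    v = theta.v_std * w70 * np.exp(eta_full[..., _IV])
    s0 = theta.s0_std * (batch.age / theta.median_age) ** theta.pwr_age * np.exp(eta_full[..., _IS0])
    ec = np.asarray(ec50, dtype=float) * np.exp(eta_full[..., _IEC])
    f_pop = theta.emax_fraction
    f_i = _expit(math.log(f_pop / (1.0 - f_pop)) + eta_full[..., _IEM])
    emax = f_i * s0
    slope = theta.slope * (1.0 + eta_full[..., _ISL])

    ce = effect_conc(batch, cl, v)
    with np.errstate(divide="ignore"):
        z = theta.gamma * (np.log(ce) - np.log(ec)[..., None])
    hill = np.where(ce > 0, _expit(np.where(ce > 0, z, 0.0)), 0.0)
    t_pos = np.maximum(batch.t_obs, 0.0)
    return s0[..., None] - emax[..., None] * hill + slope[..., None] * t_pos


def conditional_loglik(batch: SubjectBatch, theta: StructuralParams, sigma: float, eta_full, ec50):
    """log p(observations | eta) per subject, shape (..., n).

    Proportional residual: y ~ N(pred, (sigma*pred)^2). Predictions are
    floored at a small positive pressure for the density, with a smooth
    quadratic penalty steering the inner optimiser away from the floor.
    """
    with np.errstate(over="ignore", invalid="ignore", divide="ignore", under="ignore"):
        pred = predict_map(batch, theta, eta_full, ec50)
        pred_c = np.maximum(pred, _PRED_FLOOR)
        sd = sigma * pred_c
        z = (batch.y - pred_c) / sd
        ll = -0.5 * z * z - np.log(sd) - 0.5 * LOG2PI
        ll = np.sum(np.where(batch.mask, ll, 0.0), axis=-1)
        pen = np.sum(np.where(batch.mask, np.minimum(pred - _PRED_FLOOR, 0.0) ** 2, 0.0), axis=-1)
        out = ll - 1e3 * pen
    # absurd etas (overflowing the structural model) are simply very bad
    return np.where(np.isfinite(out), out, -1e12)


def _omega_vector(omega: VarianceComponents, label: str) -> np.ndarray:
    return np.array(
        [
            omega.omega_v,
            omega.omega_cl,
            omega.omega_s0,
            omega.omega_ec50(label),
            omega.omega_emax,
            omega.omega_slope,
        ]
    )


def _fd_stencil(d: int, h: float):
    """Perturbation matrix for a full central-difference gradient+Hessian."""
    pairs = [(j, k) for j in range(d) for k in range(j + 1, d)]
    M = 1 + 2 * d + 4 * len(pairs)
    P = np.zeros((M, d))
    for j in range(d):
        P[1 + 2 * j, j] = h
        P[2 + 2 * j, j] = -h
    base = 1 + 2 * d
    for m, (j, k) in enumerate(pairs):
        P[base + 4 * m, [j, k]] = (h, h)
        P[base + 4 * m + 1, [j, k]] = (h, -h)
        P[base + 4 * m + 2, [j, k]] = (-h, h)
        P[base + 4 * m + 3, [j, k]] = (-h, -h)
    return P, pairs


def _assemble(G, d, h, pairs):
    """Gradient (n, d) and Hessian (n, d, d) from stencil values (M, n)."""
    g0 = G[0]
    n = g0.shape[0]
    grad = np.empty((n, d))
    H = np.empty((n, d, d))
    for j in range(d):
        gp, gm = G[1 + 2 * j], G[2 + 2 * j]
        grad[:, j] = (gp - gm) / (2.0 * h)
        H[:, j, j] = (gp + gm - 2.0 * g0) / (h * h)
    base = 1 + 2 * d
    for m, (j, k) in enumerate(pairs):
        v = (G[base + 4 * m] - G[base + 4 * m + 1] - G[base + 4 * m + 2] + G[base + 4 * m + 3]) / (4.0 * h * h)
        H[:, j, k] = v
        H[:, k, j] = v
    return g0, grad, H


@dataclass
class LaplaceResult:
    loglik: np.ndarray  # (n,)
    eta_full: np.ndarray  # (n, 6) joint modes, zeros on inactive dims
    active: np.ndarray  # indices of active eta dims
    converged: np.ndarray  # (n,) bool


def laplace_component(
    batch: SubjectBatch,
    theta: StructuralParams,
    omega: VarianceComponents,
    label: str,
    eta_init: np.ndarray | None = None,
    *,
    gtol: float = 1e-5,
    max_iter: int = 60,
    fd_step: float = 1e-4,
) -> LaplaceResult:
    """Laplace-approximate log marginal likelihood of one mixture component.

    Maximises the joint log-density over the active random effects with a
    damped (ridge-stabilised, backtracking) Newton iteration run over all
    subjects simultaneously, then adds the Gaussian curvature correction
    0.5*log|2 pi H^{-1}| at the mode. With no active random effects this
    is exactly the conditional log-likelihood at eta = 0.
    """
    sigma = omega.sigma_prop
    if sigma <= 0:
        raise ValueError("sigma_prop must be positive to evaluate a likelihood")
    om_full = _omega_vector(omega, label)
    active = np.where(om_full > 0)[0]
    d = len(active)
    n = batch.n
    ec50 = theta.ec50(label)

    if d == 0:
        ll = conditional_loglik(batch, theta, sigma, np.zeros((n, 6)), ec50)
        return LaplaceResult(ll, np.zeros((n, 6)), active, np.ones(n, dtype=bool))

    om = om_full[active]
    prior_const = -float(np.sum(np.log(om))) - 0.5 * d * LOG2PI

    def joint(eta_red):
        full = np.zeros(eta_red.shape[:-1] + (6,))
        full[..., active] = eta_red
        ll = conditional_loglik(batch, theta, sigma, full, ec50)
        return ll + prior_const - 0.5 * np.sum((eta_red / om) ** 2, axis=-1)

    eta = np.zeros((n, d)) if eta_init is None else np.array(eta_init[:, active], dtype=float)
    P, pairs = _fd_stencil(d, fd_step)

    stuck = np.zeros(n, dtype=bool)  # no ascent at FD resolution: done
    converged = np.zeros(n, dtype=bool)
    # one stencil per iteration: the assembly at the final point doubles as
    # the curvature used in the Laplace correction
    G = joint(eta[None, :, :] + P[:, None, :])
    g0, grad, H = _assemble(G, d, fd_step, pairs)
    for _ in range(max_iter):
        gnorm = np.max(np.abs(grad), axis=1)
        converged = (gnorm < gtol) | stuck
        if converged.all():
            break
        A = -H
        w, V = np.linalg.eigh(A)
        w_ref = np.maximum(w[:, -1], 1e-3)
        w_pd = np.maximum(w, 1e-6 * w_ref[:, None])
        step = np.einsum("nij,nj->ni", V, np.einsum("nij,ni->nj", V, grad) / w_pd)
        # trust-region-style cap: no random effect moves more than 3 SD-units
        # per iteration, which keeps candidate etas in representable range
        big = np.max(np.abs(step), axis=1, keepdims=True)
        step = step * np.minimum(1.0, 3.0 / np.maximum(big, 1e-300))
        alpha = np.ones(n)
        todo = ~converged
        new_eta = eta.copy()
        for _bt in range(30):
            cand = eta + alpha[:, None] * step
            gc = joint(cand)
            improved = gc > g0 + 1e-13
            accept = todo & improved
            new_eta[accept] = cand[accept]
            todo = todo & ~improved
            if not todo.any():
                break
            alpha[todo] *= 0.5
            if alpha[todo].max() < 1e-8:
                stuck = stuck | todo
                break
        eta = new_eta
        G = joint(eta[None, :, :] + P[:, None, :])
        g0, grad, H = _assemble(G, d, fd_step, pairs)

    w, _V = np.linalg.eigh(-H)
    w_ref = np.maximum(w[:, -1], 1e-3)
    w_pd = np.maximum(w, 1e-6 * w_ref[:, None])
    logdet = np.sum(np.log(w_pd), axis=1)
    ll = g0 + 0.5 * d * LOG2PI - 0.5 * logdet

    eta_full = np.zeros((n, 6))
    eta_full[:, active] = eta
    return LaplaceResult(ll, eta_full, active, converged)


# Inner-posterior basin probes: the slope random effect (omega ~ 2) can
# trade off against the drug effect, so the joint density is multimodal
# for a minority of subjects. These seeds (slope up with faster CL, slope
# down with larger/smaller Emax) locate the alternative basins.
_EXTRA_STARTS: tuple[dict, ...] = (
    {_ISL: 1.5, _ICL: 0.8},
    {_ISL: -1.5, _IEM: 1.0},
    {_ISL: -1.5, _IEM: -1.0},
)
_BASIN_TOL = 0.15  # modes closer than this (inf-norm, eta scale) are one basin
_MAX_BASINS = 4  # per subject and component


def laplace_multimodal(
    batch: SubjectBatch,
    theta: StructuralParams,
    omega: VarianceComponents,
    label: str,
    basins: tuple[np.ndarray, np.ndarray] | None = None,
    multistart: bool = False,
    **laplace_opts,
):
    """Basin-summed Laplace marginal likelihood of one component.

    A single-mode Laplace approximation under-counts the integral when
    the subject posterior is multimodal, so the marginal likelihood here
    is the log-sum of the Laplace masses of all distinct basins found for
    each subject. ``basins`` is the cached ``(rows, eta)`` start set (one
    or more known basin modes per subject); ``multistart`` additionally
    probes the standard alternative seeds. Returns ``(result, basins)``
    where the result carries the basin-summed log-likelihood and each
    subject's best-basin mode, and ``basins`` is the refreshed cache.
    """
    n = batch.n
    if basins is None:
        rows = np.arange(n)
        eta0 = np.zeros((n, 6))
    else:
        rows, eta0 = basins
        rows = np.asarray(rows, dtype=int)
        eta0 = np.asarray(eta0, dtype=float)
    if multistart:
        extra_rows = [rows]
        extra_eta = [eta0]
        # one zero start per subject unless already present
        extra_rows.append(np.arange(n))
        extra_eta.append(np.zeros((n, 6)))
        for seed in _EXTRA_STARTS:
            init = np.zeros((n, 6))
            for dim, val in seed.items():
                init[:, dim] = val
            extra_rows.append(np.arange(n))
            extra_eta.append(init)
        rows = np.concatenate(extra_rows)
        eta0 = np.concatenate(extra_eta)

    expanded = batch.subset(rows)
    res = laplace_component(expanded, theta, omega, label, eta_init=eta0, **laplace_opts)
    active = res.active

    loglik = np.full(n, -np.inf)
    eta_best = np.zeros((n, 6))
    conv = np.ones(n, dtype=bool)
    keep_rows: list[int] = []
    keep_eta: list[np.ndarray] = []
    order = np.argsort(rows, kind="stable")
    sorted_rows = rows[order]
    boundaries = np.flatnonzero(np.r_[True, np.diff(sorted_rows) != 0])
    for b, start in enumerate(boundaries):
        stop = boundaries[b + 1] if b + 1 < len(boundaries) else len(sorted_rows)
        subj = sorted_rows[start]
        idx = order[start:stop]
        lls = res.loglik[idx]
        etas = res.eta_full[idx]
        # deduplicate converged modes into distinct basins, best first
        rank = np.argsort(-lls)
        basin_ll: list[float] = []
        basin_eta: list[np.ndarray] = []
        for r in rank:
            duplicate = any(
                len(active) == 0 or np.max(np.abs(etas[r, active] - be[active])) < _BASIN_TOL
                for be in basin_eta
            )
            if duplicate:
                continue
            basin_ll.append(lls[r])
            basin_eta.append(etas[r])
            if len(basin_ll) >= _MAX_BASINS:
                break
        arr = np.array(basin_ll)
        m = arr.max()
        loglik[subj] = m + math.log(np.exp(arr - m).sum())
        eta_best[subj] = basin_eta[0]
        conv[subj] = res.converged[idx].all()
        for be in basin_eta:
            keep_rows.append(subj)
            keep_eta.append(be)

    out = LaplaceResult(loglik, eta_best, active, conv)
    return out, (np.array(keep_rows, dtype=int), np.array(keep_eta))


def mixture_loglik(
    batch: SubjectBatch,
    theta: StructuralParams,
    omega: VarianceComponents,
    cache: dict | None = None,
    multistart: bool = False,
    **laplace_opts,
):
    """Per-subject log of the two-component marginal mixture likelihood.

    Returns (total (n,), result_low, result_high). ``cache`` maps
    component label -> the cached basin start set, updated in place.
    ``multistart`` additionally probes the alternative inner basins
    (slower; used periodically by the outer optimiser so the cached
    basins track each subject's posterior structure).
    """
    cache = cache if cache is not None else {}
    res = {}
    for label in ("low", "high"):
        res[label], cache[label] = laplace_multimodal(
            batch, theta, omega, label, cache.get(label), multistart, **laplace_opts
        )
    p = theta.p_high
    if p <= 0.0:
        total = res["low"].loglik
    elif p >= 1.0:
        total = res["high"].loglik
    else:
        total = np.logaddexp(math.log(p) + res["high"].loglik, math.log1p(-p) + res["low"].loglik)
    return total, res["low"], res["high"]
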