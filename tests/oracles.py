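"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: the
effect-compartment oracle integrates the ODE numerically instead of using
the closed form, and the marginal-likelihood oracle integrates the joint
density over the random effects on a dense grid instead of using the
Laplace approximation.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import solve_ivp

from snpkpd.kpd_core import InfusionSchedule

LOG2PI = math.log(2.0 * math.pi)


def ode_effect_concentration(schedule: InfusionSchedule, cl: float, v: float, times) -> np.ndarray:
    """Effect-compartment concentration by numerical ODE integration.

    dCe/dt = rate(t)/V - (CL/V) * Ce, integrated segment-by-segment with
    tight tolerances so discontinuities in the input never cross an
    integration step.
    """
    ke = cl / v
    times = np.asarray(times, dtype=float)
    pieces = schedule.pieces()
    knots = [t for t, _ in pieces]
    grid = np.unique(np.concatenate([[min(0.0, times.min() if times.size else 0.0)], knots, times]))
    c = 0.0
    t_prev = grid[0]
    out = {grid[0]: 0.0 if grid[0] <= knots[0] else None}
    values = {t_prev: c}
    for t_next in grid[1:]:
        mid = 0.5 * (t_prev + t_next)
        r = schedule.rate_at(mid)
        sol = solve_ivp(
            lambda _t, y: [r / v - ke * y[0]],
            (t_prev, t_next),
            [c],
            rtol=1e-11,
            atol=1e-14,
            method="DOP853",
        )
        c = float(sol.y[0, -1])
        values[t_next] = c
        t_prev = t_next
    return np.array([values[t] for t in times])


def hill_map(s0, emax, ec50, gamma, slope, ce, t):
    """Direct scalar evaluation of the response equation."""
    ce = np.asarray(ce, dtype=float)
    frac = np.where(ce > 0, ce ** gamma / (ec50 ** gamma + ce ** gamma), 0.0)
    return s0 - emax * frac + slope * np.maximum(np.asarray(t, dtype=float), 0.0)


def _toy_conditional_loglik(eta_grid, toy):
    """log p(y | eta) for a constant-infusion toy subject.

    ``eta_grid`` has shape (..., 2) holding (eta_s0, eta_cl); unused
    dimensions of the model carry no random effect in the toys.
    """
    eta_s0 = eta_grid[..., 0]
    eta_cl = eta_grid[..., 1]
    cl = toy["cl"] * np.exp(eta_cl)
    ke = cl / toy["v"]
    s0 = toy["s0"] * np.exp(eta_s0)
    t = np.asarray(toy["t_h"])  # (T,)
    ce = (toy["rate"] / cl)[..., None] * (1.0 - np.exp(-ke[..., None] * t))
    frac = ce ** toy["gamma"] / (toy["ec50"] ** toy["gamma"] + ce ** toy["gamma"])
    # the maximal effect is a fraction of the realised baseline
    pred = s0[..., None] * (1.0 - toy["emax_frac"] * frac)
    sd = toy["sigma"] * pred
    z = (toy["y"] - pred) / sd
    return np.sum(-0.5 * z * z - np.log(sd) - 0.5 * LOG2PI, axis=-1)


def grid_marginal_loglik(toy, omegas: dict, n_points: int = 3001, half_width: float = 8.0) -> float:
    """Marginal log-likelihood of a toy subject by dense-grid quadrature.

    ``omegas`` maps random-effect name ('s0', 'cl') to its SD; one or two
    entries. Trapezoidal integration of p(y|eta) N(eta; 0, omega^2) over
    a wide grid, in one or two dimensions.
    """
    dims = list(omegas)
    if len(dims) == 1:
        om = omegas[dims[0]]
        g = np.linspace(-half_width * om, half_width * om, n_points)
        eta = np.zeros((n_points, 2))
        eta[:, 0 if dims[0] == "s0" else 1] = g
        ll = _toy_conditional_loglik(eta, toy)
        log_prior = -0.5 * (g / om) ** 2 - math.log(om) - 0.5 * LOG2PI
        log_int = ll + log_prior
        m = log_int.max()
        return float(m + np.log(np.trapezoid(np.exp(log_int - m), g)))
    if len(dims) == 2:
        om_a, om_b = omegas[dims[0]], omegas[dims[1]]
        n2 = min(n_points, 501)
        ga = np.linspace(-half_width * om_a, half_width * om_a, n2)
        gb = np.linspace(-half_width * om_b, half_width * om_b, n2)
        A, B = np.meshgrid(ga, gb, indexing="ij")
        eta = np.zeros(A.shape + (2,))
        eta[..., 0 if dims[0] == "s0" else 1] = A
        eta[..., 0 if dims[1] == "s0" else 1] = B
        ll = _toy_conditional_loglik(eta, toy)
        log_prior = (
            -0.5 * (A / om_a) ** 2
            - math.log(om_a)
            - 0.5 * (B / om_b) ** 2
            - math.log(om_b)
            - LOG2PI
        )
        log_int = ll + log_prior
        m = log_int.max()
        inner = np.trapezoid(np.exp(log_int - m), gb, axis=1)
        return float(m + np.log(np.trapezoid(inner, ga)))
    raise ValueError("one or two random effects only")
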