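"""Estimation-layer tests: Laplace accuracy, OFV behaviour, fitting."""

import dataclasses
import math

import numpy as np
import pytest

from oracles import grid_marginal_loglik
from snpkpd.estimation import (
    bootstrap_fit,
    empirical_bayes,
    fit_model,
    likelihood_ratio_test,
    subject_marginal_likelihood,
    total_ofv,
)
from snpkpd.population import VarianceComponents
from snpkpd.trial import DEFAULT_DESIGN, EventRecord, simulate_trial

LOG2PI = math.log(2.0 * math.pi)


def _toy_subject(theta, sigma, omega_s0=0.0, omega_cl=0.0, rng=None, n_obs=3):
    """One subject on a constant 1 µg/kg/min infusion with a few observations."""
    rng = rng or np.random.default_rng(0)
    age, wt = 8.0, 30.0
    cl = theta.cl_std * (wt / 70.0) ** 0.75
    v = theta.v_std * wt / 70.0
    s0 = theta.s0_std * (age / theta.median_age) ** theta.pwr_age
    rate = 1.0 * wt * 60.0
    t_min = np.linspace(4.0, 28.0, n_obs)
    t_h = t_min / 60.0
    ke = cl / v
    ce = (rate / cl) * (1.0 - np.exp(-ke * t_h))
    frac = ce ** theta.gamma / (theta.ec50_low ** theta.gamma + ce ** theta.gamma)
    pred = s0 - theta.emax_fraction * s0 * frac
    y = pred * (1.0 + rng.normal(0, sigma, n_obs))
    records = [
        EventRecord(1, 0.0, "dose_start", rate=1.0, map_obs=None, weight=wt, age=age, arm=1.0),
        EventRecord(1, 40.0, "dose_stop", rate=0.0, map_obs=None, weight=wt, age=age, arm=1.0),
    ] + [
        EventRecord(1, float(t), "observation", rate=None, map_obs=float(val), weight=wt, age=age, arm=1.0)
        for t, val in zip(t_min, y)
    ]
    toy = {
        "cl": cl, "v": v, "s0": s0, "rate": rate, "t_h": t_h, "y": y,
        "gamma": theta.gamma, "ec50": theta.ec50_low, "emax": theta.emax_fraction * s0,
        "emax_frac": theta.emax_fraction, "sigma": sigma,
    }
    omega = VarianceComponents(omega_s0=omega_s0, omega_cl=omega_cl, sigma_prop=sigma)
    return records, toy, omega


def _slopeless(theta):
    """Toys carry no progression term; the oracle model matches by slope ~ 0."""
    return dataclasses.replace(theta, slope=1e-12)


class TestLaplaceAgainstQuadrature:
    def test_single_random_effect(self, table2):
        theta = _slopeless(table2[0])
        records, toy, omega = _toy_subject(theta, sigma=0.05, omega_s0=0.15)
        lap = subject_marginal_likelihood(records, theta, omega, "low")
        ref = grid_marginal_loglik(toy, {"s0": 0.15})
        assert abs(lap - ref) <= 1e-3

    def test_two_random_effects(self, table2):
        theta = _slopeless(table2[0])
        records, toy, omega = _toy_subject(theta, sigma=0.05, omega_s0=0.15, omega_cl=0.3)
        lap = subject_marginal_likelihood(records, theta, omega, "low")
        ref = grid_marginal_loglik(toy, {"s0": 0.15, "cl": 0.3})
        assert abs(lap - ref) <= 1e-3

    def test_no_random_effect_collapses_to_normal_density(self, table2):
        theta = _slopeless(table2[0])
        records, toy, omega = _toy_subject(theta, sigma=0.2, n_obs=1)
        # observation placed exactly at the prediction
        obs = [r for r in records if r.is_observation][0]
        ce = toy["rate"] / toy["cl"] * (1.0 - math.exp(-(toy["cl"] / toy["v"]) * obs.time / 60.0))
        frac = ce ** toy["gamma"] / (toy["ec50"] ** toy["gamma"] + ce ** toy["gamma"])
        pred = toy["s0"] - toy["emax"] * frac
        records = [r if not r.is_observation else dataclasses.replace(r, map_obs=pred) for r in records]
        lap = subject_marginal_likelihood(records, theta, omega, "low")
        expected = -math.log(0.2 * pred) - 0.5 * LOG2PI
        assert lap == pytest.approx(expected, abs=1e-9)


class TestTotalOfv:
    def test_mixture_collapse_at_p_one(self, simulated_records, table2):
        theta, omega = table2
        theta1 = dataclasses.replace(theta, p_high=1.0)
        # with p_high = 1 the OFV must equal the pure high-component OFV,
        # which the low component's parameters cannot influence
        ofv_a = total_ofv(simulated_records, theta1, omega)
        theta2 = dataclasses.replace(theta1, ec50_low=50.0)
        ofv_b = total_ofv(simulated_records, theta2, omega)
        assert ofv_a == pytest.approx(ofv_b, abs=1e-6)

    def test_row_order_invariance(self, simulated_records, table2):
        theta, omega = table2
        rng = np.random.default_rng(0)
        shuffled = list(simulated_records)
        rng.shuffle(shuffled)
        assert total_ofv(shuffled, theta, omega) == pytest.approx(
            total_ofv(simulated_records, theta, omega), abs=1e-6
        )

    def test_component_swap_identifiability(self, table2):
        theta, omega = table2
        design = dataclasses.replace(DEFAULT_DESIGN, n_subjects=60)
        recs = simulate_trial(design, theta, omega, np.random.default_rng(17))
        swapped = dataclasses.replace(
            theta, ec50_low=theta.ec50_low, ec50_high=theta.ec50_high, p_high=1.0 - theta.p_high
        )
        # mixture probability flipped against the true component weights
        assert total_ofv(recs, theta, omega) <= total_ofv(recs, swapped, omega)

    def test_empty_dataset_rejected(self, table2):
        theta, omega = table2
        with pytest.raises(ValueError):
            total_ofv([], theta, omega)


class TestFitModel:
    def test_near_noiseless_recovery(self, table2):
        theta, _ = table2
        design = dataclasses.replace(DEFAULT_DESIGN, n_subjects=50)
        tiny = VarianceComponents(sigma_prop=1e-3)
        recs = simulate_trial(design, theta, tiny, np.random.default_rng(23))
        init = dataclasses.replace(
            theta, cl_std=theta.cl_std * 1.05, s0_std=theta.s0_std * 0.97, gamma=theta.gamma * 1.1
        )
        fixed = {"v_std", "omega_v", "omega_cl", "omega_s0", "omega_ec50_low",
                 "omega_ec50_high", "omega_emax", "omega_slope"}
        fit = fit_model(recs, init, tiny, fixed=fixed, compute_ebe=False, maxfun=150)
        assert fit.theta_hat.cl_std == pytest.approx(theta.cl_std, rel=0.01)
        assert fit.theta_hat.s0_std == pytest.approx(theta.s0_std, rel=0.01)
        assert fit.theta_hat.gamma == pytest.approx(theta.gamma, rel=0.01)

    def test_nesting_never_hurts(self, table2):
        # checked without random effects so the objective is deterministic
        # and both problems are optimised to convergence
        theta, _ = table2
        design = dataclasses.replace(DEFAULT_DESIGN, n_subjects=20)
        quiet = VarianceComponents(sigma_prop=0.05)
        recs = simulate_trial(design, theta, quiet, np.random.default_rng(31))
        base_fixed = {"v_std", "omega_v", "omega_cl", "omega_s0", "omega_ec50_low",
                      "omega_ec50_high", "omega_emax", "omega_slope", "ec50_low",
                      "ec50_delta", "gamma", "slope", "p_high", "emax_frac", "pwr_age"}
        reduced = fit_model(recs, theta, quiet, fixed=base_fixed | {"cl_std"},
                            compute_ebe=False, maxfun=80)
        full = fit_model(recs, theta, quiet, fixed=base_fixed, compute_ebe=False, maxfun=80)
        assert full.ofv <= reduced.ofv + 1e-4

    def test_unknown_fixed_name_rejected(self, simulated_records, table2):
        theta, omega = table2
        with pytest.raises(ValueError, match="unknown parameter"):
            fit_model(simulated_records, theta, omega, fixed={"v_std", "nonsense"})


class TestEmpiricalBayes:
    def test_p_one_gives_unit_responsibility(self, simulated_records, table2):
        theta, omega = table2
        ebe = empirical_bayes(simulated_records, dataclasses.replace(theta, p_high=1.0), omega)
        assert np.allclose(ebe["resp_high"], 1.0)

    def test_responsibilities_lie_in_unit_interval(self, simulated_records, table2):
        theta, omega = table2
        ebe = empirical_bayes(simulated_records, theta, omega)
        assert ((ebe["resp_high"] >= 0) & (ebe["resp_high"] <= 1)).all()

    def test_sensitive_subject_classified_low(self, table2):
        theta, omega = table2
        # simulate truth purely from the low-EC50 (sensitive) component
        low_theta = dataclasses.replace(theta, p_high=0.0)
        quiet = VarianceComponents(sigma_prop=0.05)
        design = dataclasses.replace(DEFAULT_DESIGN, arms=(1.0,), n_subjects=8,
                                     map_floor=1.0, map_floor_neonate=1.0)
        recs = simulate_trial(design, low_theta, quiet, np.random.default_rng(2))
        ebe = empirical_bayes(recs, theta, quiet)
        assert (ebe["resp_high"] < 0.5).mean() >= 0.75


class TestBootstrap:
    def test_identity_resample_reproduces_fit(self, table2):
        theta, omega = table2
        design = dataclasses.replace(DEFAULT_DESIGN, n_subjects=15)
        recs = simulate_trial(design, theta, omega, np.random.default_rng(41))
        fixed = {"v_std", "pwr_age", "gamma", "slope", "p_high", "emax_frac",
                 "ec50_low", "ec50_delta", "omega_v", "omega_cl", "omega_s0",
                 "omega_ec50_low", "omega_ec50_high", "omega_emax", "omega_slope"}
        base = fit_model(recs, theta, omega, fixed=fixed, compute_ebe=False, maxfun=40)
        boot = bootstrap_fit(
            recs, 1, np.random.default_rng(1), base_fit=base,
            resampler=lambda n, rep: np.arange(n), maxiter=100,
        )
        assert boot.n_converged == 1
        assert boot.estimates["cl_std"].iloc[0] == pytest.approx(base.theta_hat.cl_std, rel=1e-3)
        assert boot.estimates["s0_std"].iloc[0] == pytest.approx(base.theta_hat.s0_std, rel=1e-3)

    def test_summary_table_structure(self, table2):
        theta, omega = table2
        design = dataclasses.replace(DEFAULT_DESIGN, n_subjects=12)
        recs = simulate_trial(design, theta, omega, np.random.default_rng(43))
        fixed = {"v_std", "pwr_age", "gamma", "slope", "p_high", "emax_frac",
                 "ec50_low", "ec50_delta", "omega_v", "omega_cl", "omega_s0",
                 "omega_ec50_low", "omega_ec50_high", "omega_emax", "omega_slope"}
        base = fit_model(recs, theta, omega, fixed=fixed, compute_ebe=False, maxfun=30)
        boot = bootstrap_fit(recs, 3, np.random.default_rng(2), base_fit=base, maxiter=60)
        assert set(boot.table.columns) == {"estimate", "mean", "rse_pct", "ci_lo", "ci_hi"}
        free_rows = boot.table.loc[["cl_std", "s0_std", "sigma_prop"]]
        assert np.isfinite(free_rows["mean"]).all()


class TestLikelihoodRatio:
    def test_chi_square_quantile(self):
        assert likelihood_ratio_test(103.84, 100.0, 1) == pytest.approx(0.05, abs=2e-3)

    def test_zero_delta_gives_one(self):
        assert likelihood_ratio_test(100.0, 100.0, 1) == 1.0

    def test_ordering_violation_raises(self):
        with pytest.raises(ValueError):
            likelihood_ratio_test(99.0, 100.0, 1)
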