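"""Model evaluation: visual predictive check and goodness-of-fit tables.

The VPC keeps every subject's realised design fixed (dose history,
observation times, covariates), redraws random effects, mixture labels
and residuals from the model, and compares observed percentiles per time
bin with the spread of the same percentiles across simulated replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._batch import ETA_DIMS, SubjectBatch, predict_map
from .estimation import FitResult, empirical_bayes
from .kpd_core import StructuralParams
from .population import VarianceComponents

__all__ = ["VpcResult", "vpc", "gof_tables"]

_MIN_BIN_OBS = 5


@dataclass
class VpcResult:
    """Observed percentiles and simulated confidence bands per time bin.

    ``table`` columns: ``time_min``, ``n_obs``, ``sparse`` (fewer than 5
    observations), ``obs_p<q>`` for each percentile and
    ``sim_p<q>_lo``/``sim_p<q>_hi`` for the simulated interval around it.
    """

    table: pd.DataFrame
    n_replicates: int
    percentiles: tuple[float, ...]
    stratum: str | None = None

    def coverage(self, q: float = 50) -> float:
        """Fraction of non-sparse bins whose observed percentile falls
        inside its simulated band."""
        t = self.table[~self.table["sparse"]]
        ok = (t[f"obs_p{q:g}"] >= t[f"sim_p{q:g}_lo"]) & (t[f"obs_p{q:g}"] <= t[f"sim_p{q:g}_hi"])
        return float(ok.mean())


def _draw_replicates(
    batch: SubjectBatch,
    theta: StructuralParams,
    omega: VarianceComponents,
    n_replicates: int,
    rng: np.random.Generator,
):
    """Simulate (R, n, T) observations on the recorded designs.

    Returns (y_rep, labels) where labels is the (R, n) array of redrawn
    mixture assignments.
    """
    n = batch.n
    R = n_replicates
    high = rng.random((R, n)) < theta.p_high
    om = np.array([omega.omega_v, omega.omega_cl, omega.omega_s0, 1.0, omega.omega_emax, omega.omega_slope])
    eta = rng.standard_normal((R, n, 6)) * om
    om_ec = np.where(high, omega.omega_ec50_high, omega.omega_ec50_low)
    eta[..., 3] = rng.standard_normal((R, n)) * om_ec
    ec50 = np.where(high, theta.ec50_high, theta.ec50_low)
    pred = predict_map(batch, theta, eta, ec50)
    pred = np.maximum(pred, 1e-3)
    y = pred * (1.0 + rng.standard_normal(pred.shape) * omega.sigma_prop)
    # match the generator: residuals are redrawn until positive
    for _ in range(100):
        bad = (y <= 0) & batch.mask
        if not bad.any():
            break
        y[bad] = pred[bad] * (1.0 + rng.standard_normal(int(bad.sum())) * omega.sigma_prop)
    return y, high


def _vpc_table(batch, y_obs, y_rep, subj_sel, rep_sel, percentiles, ci):
    """Percentile table over time bins for one stratum.

    ``subj_sel`` (n,) selects observed subjects; ``rep_sel`` (R, n)
    selects subject-replicates for the simulated bands.
    """
    t_min = np.round(batch.t_obs * 60.0, 6)
    obs_mask = batch.mask & subj_sel[:, None]
    bins = np.unique(t_min[obs_mask])
    lo_q, hi_q = (100 - ci) / 2.0, 100 - (100 - ci) / 2.0
    rows = []
    for b in bins:
        cell = obs_mask & (t_min == b)
        vals = y_obs[cell]
        n_obs = vals.size
        row = {"time_min": float(b), "n_obs": int(n_obs), "sparse": n_obs < _MIN_BIN_OBS}
        obs_q = np.percentile(vals, percentiles)
        rep_cell = batch.mask & (t_min == b)  # (n, T)
        for q, oq in zip(percentiles, obs_q):
            row[f"obs_p{q:g}"] = float(oq)
        # per replicate: percentile over the selected subject-observations
        R = y_rep.shape[0]
        sim_q = np.full((R, len(percentiles)), np.nan)
        for r in range(R):
            sel = rep_cell & rep_sel[r][:, None]
            v = y_rep[r][sel]
            if v.size:
                sim_q[r] = np.percentile(v, percentiles)
        for j, q in enumerate(percentiles):
            col = sim_q[:, j]
            col = col[~np.isnan(col)]
            if col.size:
                row[f"sim_p{q:g}_lo"] = float(np.percentile(col, lo_q))
                row[f"sim_p{q:g}_hi"] = float(np.percentile(col, hi_q))
            else:
                row[f"sim_p{q:g}_lo"] = np.nan
                row[f"sim_p{q:g}_hi"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def vpc(
    dataset,
    theta: StructuralParams,
    omega: VarianceComponents,
    n_replicates: int = 100,
    rng: np.random.Generator | None = None,
    *,
    stratify_by_mixture: bool = False,
    percentiles: tuple[float, ...] = (5.0, 50.0, 95.0),
    ci: float = 95.0,
):
    """Visual predictive check.

    Simulates ``n_replicates`` datasets on the observed designs and
    returns observed 5th/50th/95th percentiles per time bin together
    with the 95% interval of each percentile across replicates. Bins
    default to the observation grid; bins with fewer than 5 observations
    are flagged ``sparse``. With ``stratify_by_mixture`` a dict of
    per-component results is returned, splitting observed subjects by the
    recorded simulation truth and replicate draws by their redrawn labels.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be at least 2")
    if rng is None:
        rng = np.random.default_rng()
    batch = dataset if isinstance(dataset, SubjectBatch) else SubjectBatch.from_records(dataset)
    y_rep, high = _draw_replicates(batch, theta, omega, n_replicates, rng)

    if not stratify_by_mixture:
        all_subj = np.ones(batch.n, dtype=bool)
        all_rep = np.ones((n_replicates, batch.n), dtype=bool)
        table = _vpc_table(batch, batch.y, y_rep, all_subj, all_rep, percentiles, ci)
        return VpcResult(table, n_replicates, tuple(percentiles))

    if any(m is None for m in batch.mixture):
        raise ValueError("stratified VPC needs recorded mixture labels in the dataset")
    out = {}
    labels = np.array(batch.mixture)
    for label, rep_mask in (("low", ~high), ("high", high)):
        subj_sel = labels == label
        table = _vpc_table(batch, batch.y, y_rep, subj_sel, rep_mask, percentiles, ci)
        out[label] = VpcResult(table, n_replicates, tuple(percentiles), stratum=label)
    return out


def gof_tables(fit: FitResult, dataset) -> pd.DataFrame:
    """Observation-level goodness-of-fit table.

    PRED is the population prediction (eta = 0) under each subject's most
    probable mixture component; IPRED uses the empirical Bayes modes of
    that component. Weighted residuals divide by the proportional error
    SD at the corresponding prediction.
    """
    batch = dataset if isinstance(dataset, SubjectBatch) else SubjectBatch.from_records(dataset)
    theta, omega = fit.theta_hat, fit.omega_hat
    ebe = fit.ebe
    if ebe is None or len(ebe) != batch.n or not np.array_equal(ebe["subject_id"].to_numpy(), batch.ids):
        ebe = empirical_bayes(batch, theta, omega)

    label = ebe["label"].to_numpy()
    ec50 = np.where(label == "high", theta.ec50_high, theta.ec50_low)
    eta_hat = np.zeros((batch.n, 6))
    for j, dim in enumerate(ETA_DIMS):
        eta_hat[:, j] = np.where(label == "high", ebe[f"eta_{dim}_high"], ebe[f"eta_{dim}_low"])

    pred = predict_map(batch, theta, np.zeros((batch.n, 6)), ec50)
    ipred = predict_map(batch, theta, eta_hat, ec50)
    sigma = omega.sigma_prop

    rows = []
    for i in range(batch.n):
        for j in np.flatnonzero(batch.mask[i]):
            dv = batch.y[i, j]
            p, ip = pred[i, j], ipred[i, j]
            rows.append(
                {
                    "subject_id": batch.ids[i],
                    "time_min": batch.t_obs[i, j] * 60.0,
                    "dv": dv,
                    "pred": p,
                    "ipred": ip,
                    "res": dv - p,
                    "wres": (dv - p) / (sigma * p),
                    "ires": dv - ip,
                    "iwres": (dv - ip) / (sigma * ip),
                    "label": label[i],
                    "resp_high": ebe["resp_high"].iloc[i],
                }
            )
    return pd.DataFrame(rows)
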