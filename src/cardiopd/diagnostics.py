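"""Model evaluation: GOF tables, prediction-corrected VPC, NPDE, and the
clinical LVEF-decline classifier.

The pcVPC simulates replicate datasets at the observed design, corrects
observed and simulated values by the ratio of the bin-median population
prediction to each record's population prediction, and compares observed
5th/50th/95th percentiles per time bin against the simulation distribution
of the same percentiles.  NPDE follows the standard decorrelated
definition: each subject's observation vector is whitened with the
Cholesky factor of its simulated covariance, ranks within the simulated
predictive sample are mapped through the standard normal quantile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .likelihood import (MarginalLikelihood, OmegaMatrix, SigmaParams,
                         simulate_observations)
from .models import NlmeModel


@dataclass
class VPCResult:
    """Prediction-corrected percentile bands with simulation CIs per bin."""
    table: pd.DataFrame   # bin, time, n, p5/p50/p95 observed, CI bounds
    n_sim: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class NPDEResult:
    npde: np.ndarray          # one per observation (model order)
    mean: float
    variance: float
    normality_statistic: float   # Shapiro-Wilk W
    normality_pvalue: float
    decorrelated: bool

    def summary(self) -> dict:
        return {"mean": self.mean, "variance": self.variance,
                "shapiro_w": self.normality_statistic,
                "shapiro_p": self.normality_pvalue,
                "decorrelated": self.decorrelated}


def _default_bins(times: np.ndarray, max_bins: int = 11):
    """Bin ids over time.

    Uses the unique nominal times when the grid is small (shared protocol
    visits); otherwise quantile bins, so subject-relative visit schedules
    still pool comparable numbers of observations per bin.
    """
    rounded = np.round(times, 6)
    uniq = np.unique(rounded)
    if uniq.size <= max_bins:
        return np.searchsorted(uniq, rounded), uniq
    qs = np.quantile(times, np.linspace(0, 1, max_bins + 1))
    edges = np.unique(qs)
    ids = np.clip(np.searchsorted(edges, times, side="right") - 1,
                  0, edges.size - 2)
    centers = np.array([times[ids == b].mean() if (ids == b).any()
                        else 0.5 * (edges[b] + edges[b + 1])
                        for b in range(edges.size - 1)])
    return ids, centers


def pcvpc(model: NlmeModel, theta, omega: OmegaMatrix, sigma: SigmaParams,
          n_sim: int = 500, bins: Sequence[float] | None = None,
          seed: int = 0, percentiles=(5.0, 50.0, 95.0),
          ci: float = 95.0, lloq: float | None = None) -> VPCResult:
    """Prediction-corrected visual predictive check.

    ``bins``: optional bin edges over time; by default unique nominal times
    (or quantile bins when visit times are subject-relative).  ``lloq``:
    apply the LLOQ/2 substitution to simulated replicates, matching the
    handling of the observed data.  Empty bins are dropped with a warning.
    """
    if n_sim < 2:
        raise ValueError("n_sim must be >= 2")
    m = model
    theta = dict(theta)
    rng = np.random.default_rng(seed)
    times = m.obs_times
    if bins is None:
        bin_ids, bin_time = _default_bins(times)
        n_bins = bin_time.size
    else:
        edges = np.asarray(bins, dtype=float)
        bin_ids = np.clip(np.digitize(times, edges) - 1, 0, edges.size - 2)
        bin_time = 0.5 * (edges[:-1] + edges[1:])
        n_bins = edges.size - 1

    cache = m.make_cache(theta)
    pred = m.predict(theta, cache, np.zeros((m.n_subjects, len(m.eta_names))))
    sims = simulate_observations(m, theta, omega, sigma, rng,
                                 n_replicates=n_sim, lloq=lloq)

    rows = []
    alpha = (100.0 - ci) / 2.0
    for b in range(n_bins):
        mask = bin_ids == b
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"empty VPC bin {b}; dropped", stacklevel=2)
            continue
        med_pred = np.median(pred[mask])
        corr = med_pred / pred[mask]
        obs_pc = m.y[mask] * corr
        sim_pc = sims[:, mask] * corr[None, :]
        row = {"bin": b, "time": float(bin_time[b]) if bins is None else float(bin_time[b]),
               "n": n}
        for p in percentiles:
            row[f"obs_p{p:g}"] = float(np.percentile(obs_pc, p))
            sim_stat = np.percentile(sim_pc, p, axis=1)   # one per replicate
            row[f"sim_p{p:g}_lo"] = float(np.percentile(sim_stat, alpha))
            row[f"sim_p{p:g}_med"] = float(np.percentile(sim_stat, 50))
            row[f"sim_p{p:g}_hi"] = float(np.percentile(sim_stat, 100 - alpha))
        rows.append(row)
    return VPCResult(table=pd.DataFrame(rows), n_sim=n_sim)


def npde(model: NlmeModel, theta, omega: OmegaMatrix, sigma: SigmaParams,
         n_sim: int = 1000, seed: int = 0,
         lloq: float | None = None) -> NPDEResult:
    """Normalized prediction distribution errors for every observation.

    ``lloq`` applies the LLOQ/2 substitution to the simulated replicates so
    that censored observed values are ranked against identically handled
    simulations."""
    m = model
    theta = dict(theta)
    rng = np.random.default_rng(seed)
    sims = simulate_observations(m, theta, omega, sigma, rng,
                                 n_replicates=n_sim, lloq=lloq)
    k = n_sim
    out = np.empty(m.n_obs)
    decorrelated = True
    for s in range(m.n_subjects):
        mask = m.subj_idx == s
        y_s = m.y[mask]
        sim_s = sims[:, mask]                      # (K, n_i)
        mu = sim_s.mean(axis=0)
        yc = y_s - mu
        simc = sim_s - mu[None, :]
        if y_s.size > 1:
            cov = np.cov(sim_s, rowvar=False)
            try:
                chol = np.linalg.cholesky(cov)
                yd = np.linalg.solve(chol, yc)
                simd = np.linalg.solve(chol, simc.T).T
            except np.linalg.LinAlgError:
                warnings.warn("singular simulated covariance; falling back to "
                              "non-decorrelated pd", stacklevel=2)
                decorrelated = False
                yd, simd = yc, simc
        else:
            yd, simd = yc, simc
        pd_i = (simd < yd[None, :]).sum(axis=0) / k
        pd_i = np.clip(pd_i, 1.0 / (k + 1), k / (k + 1.0))
        out[mask] = stats.norm.ppf(pd_i)
    if out.size >= 3:
        w, p = stats.shapiro(out if out.size <= 5000 else out[:5000])
    else:
        w, p = np.nan, np.nan
    return NPDEResult(npde=out, mean=float(out.mean()),
                      variance=float(out.var(ddof=1)) if out.size > 1 else float("nan"),
                      normality_statistic=float(w), normality_pvalue=float(p),
                      decorrelated=decorrelated)


def gof_table(model: NlmeModel, theta, omega: OmegaMatrix,
              sigma: SigmaParams, ebes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-observation goodness-of-fit table.

    Population predictions at eta = 0, individual predictions at the
    empirical Bayes estimates; IWRES standardizes the individual residual
    by the residual-model SD.
    """
    m = model
    theta = dict(theta)
    if ebes is None:
        from .fitting import empirical_bayes
        ebes = empirical_bayes(m, theta, omega, sigma)
    eta_cols = [f"eta_{n}" for n in m.eta_names]
    eta = ebes.set_index("ID").loc[list(m.subject_ids), eta_cols].to_numpy(float)
    cache = m.make_cache(theta)
    pred = m.predict(theta, cache, np.zeros_like(eta))
    ipred = m.predict(theta, cache, eta)
    res = m.y - pred
    ires = m.y - ipred
    iwres = ires / np.sqrt(sigma.variance(ipred))
    return pd.DataFrame({
        "ID": [m.subject_ids[i] for i in m.subj_idx],
        "time": m.obs_times, "observed": m.y, "pred": pred, "ipred": ipred,
        "residual": res, "iresidual": ires, "iwres": iwres,
    })


def classify_lvef_decline(baseline_lvef: float, lvef_series,
                          floor: float = 0.45, drop: float = 0.15) -> bool:
    """Clinically relevant LVEF decline.

    True iff any follow-up value is below ``floor`` (45%) or has dropped by
    ``drop`` (15 LVEF percentage points, absolute) or more from baseline.
    """
    series = np.atleast_1d(np.asarray(lvef_series, dtype=float))
    if series.size == 0:
        raise ValueError("need at least one follow-up LVEF value")
    vals = np.append(series, baseline_lvef)
    if ((vals <= 0) | (vals > 1)).any():
        raise ValueError("LVEF values must be fractions in (0, 1]")
    eps = 1e-12
    return bool((series < floor).any()
                or (baseline_lvef - series >= drop - eps).any())
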