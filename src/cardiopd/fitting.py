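"""Maximum-likelihood fitting of the population models.

Fixed effects are optimized on the log scale (positivity by construction;
power exponents stay untransformed), the omega matrix through its Cholesky
factor (log-diagonal), and the residual SD on the log scale.  The outer
optimizer is quasi-Newton (L-BFGS-B) over the Laplace OFV; relative
standard errors come from the inverse observed Fisher information at the
optimum via the delta method.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _numdiff
from .likelihood import (ADDITIVE, PROPORTIONAL, MarginalLikelihood,
                         OmegaMatrix, SigmaParams, correlation_from_omega)
from .models import NlmeModel

__all__ = [
    "FitResult", "fit", "empirical_bayes", "shrinkage",
    "individual_parameters", "correlation_from_omega",
]


def individual_parameters(theta: Mapping[str, float],
                          eta: Mapping[str, float]) -> dict[str, float]:
    """Apply ``P_i = P_pop * exp(eta_i)`` to every random-effect-bearing
    parameter; parameters without an eta pass through unchanged."""
    unknown = set(eta) - set(theta)
    if unknown:
        raise ValueError(f"etas {sorted(unknown)} have no matching parameter")
    return {k: (v * np.exp(eta[k]) if k in eta else v) for k, v in theta.items()}


@dataclass
class FitResult:
    theta: dict[str, float]
    omega: OmegaMatrix
    sigma: SigmaParams
    ofv: float
    rse: dict[str, float] = field(default_factory=dict)
    ebes: pd.DataFrame | None = None
    eta_shrinkage: dict[str, float] = field(default_factory=dict)
    eps_shrinkage: float = float("nan")
    convergence_status: str = "converged"
    n_subjects: int = 0
    n_obs: int = 0
    n_parameters: int = 0

    def to_json(self, path) -> None:
        payload = {
            "theta": self.theta,
            "omega": {"names": list(self.omega.names),
                      "matrix": self.omega.matrix.tolist(),
                      "cv_percent": self.omega.cv_percent()},
            "sigma": {"kind": self.sigma.kind, "sd": self.sigma.sd},
            "ofv": self.ofv,
            "rse_percent": self.rse,
            "eta_shrinkage_percent": self.eta_shrinkage,
            "eps_shrinkage_percent": self.eps_shrinkage,
            "convergence_status": self.convergence_status,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, allow_nan=True)

    def ebes_to_csv(self, path) -> None:
        if self.ebes is not None:
            self.ebes.to_csv(path, index=False)


class _Packer:
    """Bijection between (theta, omega, sigma) and the optimizer vector."""

    def __init__(self, model: NlmeModel, omega: OmegaMatrix, sigma: SigmaParams,
                 estimate_omega: bool = True, estimate_sigma: bool = True):
        self.model = model
        self.theta_names = model.theta_names
        self.transforms = model.theta_transforms
        self.omega_names = omega.names
        self.sigma_kind = sigma.kind
        self.estimate_omega = estimate_omega
        self.estimate_sigma = estimate_sigma
        q = len(omega.names)
        self._tril = np.tril_indices(q)
        # structural zeros in omega (absent random effects) stay zero
        self._omega_mask = np.diag(omega.matrix) > 0

    def pack(self, theta, omega: OmegaMatrix, sigma: SigmaParams) -> np.ndarray:
        x = []
        for n in self.theta_names:
            v = theta[n]
            x.append(np.log(v) if self.transforms.get(n, "log") == "log" else v)
        if self.estimate_omega:
            chol = np.linalg.cholesky(omega.matrix + np.diag(~self._omega_mask * 1.0))
            for i, j in zip(*self._tril):
                if not (self._omega_mask[i] and self._omega_mask[j]):
                    continue
                x.append(np.log(chol[i, i]) if i == j else chol[i, j])
        if self.estimate_sigma:
            x.append(np.log(sigma.sd))
        return np.array(x, dtype=float)

    def unpack(self, x: np.ndarray):
        pos = 0
        theta = {}
        for n in self.theta_names:
            v = x[pos]
            theta[n] = float(np.exp(v)) if self.transforms.get(n, "log") == "log" else float(v)
            pos += 1
        q = len(self.omega_names)
        chol = np.zeros((q, q))
        if self.estimate_omega:
            for i, j in zip(*self._tril):
                if not (self._omega_mask[i] and self._omega_mask[j]):
                    continue
                chol[i, j] = np.exp(x[pos]) if i == j else x[pos]
                pos += 1
            omega = OmegaMatrix(self.omega_names, chol @ chol.T)
        else:
            omega = self._fixed_omega
        if self.estimate_sigma:
            sigma = SigmaParams(sd=float(np.exp(x[pos])), kind=self.sigma_kind)
            pos += 1
        else:
            sigma = self._fixed_sigma
        return theta, omega, sigma

    def natural(self, x: np.ndarray) -> tuple[list[str], np.ndarray]:
        """Natural-scale parameter vector for RSE reporting."""
        theta, omega, sigma = self.unpack(x)
        names = list(self.theta_names)
        vals = [theta[n] for n in names]
        if self.estimate_omega:
            for k, n in enumerate(self.omega_names):
                if self._omega_mask[k]:
                    names.append(f"omega2_{n}")
                    vals.append(omega.matrix[k, k])
        if self.estimate_sigma:
            names.append("sigma")
            vals.append(sigma.sd)
        return names, np.array(vals)


def fit(model: NlmeModel,
        start_theta: Mapping[str, float] | None = None,
        start_omega: OmegaMatrix | None = None,
        start_sigma: SigmaParams | None = None,
        estimate_rse: bool = True,
        compute_ebes: bool = True,
        maxiter: int = 400,
        ftol: float = 1e-11,
        seed: int | None = None) -> FitResult:
    """Fit the population model by maximizing the Laplace marginal likelihood.

    ``seed`` is accepted for interface uniformity; the estimator itself is
    deterministic.  Convergence: relative OFV change below 1e-6 (via the
    optimizer's function tolerance) and small projected gradient.
    """
    if start_theta is None:
        start_theta = model.start_theta()
    if start_omega is None:
        start_omega = OmegaMatrix.diagonal(model.eta_names,
                                           [0.09] * len(model.eta_names))
    if start_sigma is None:
        start_sigma = SigmaParams(sd=0.2, kind=PROPORTIONAL)
    if model.n_subjects < 2 and np.any(np.diag(start_omega.matrix) > 0):
        warnings.warn("between-subject variability is not identifiable from a "
                      "single subject", stacklevel=2)

    engine = MarginalLikelihood(model, sigma_kind=start_sigma.kind)
    packer = _Packer(model, start_omega, start_sigma)
    packer._fixed_omega = start_omega
    packer._fixed_sigma = start_sigma
    x0 = packer.pack(dict(start_theta), start_omega, start_sigma)

    def objective(x):
        try:
            theta, omega, sigma = packer.unpack(x)
        except ValueError:
            return 1e12
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            val = engine.ofv(theta, omega, sigma)
        return val if np.isfinite(val) else 1e12

    ofv0 = objective(x0)
    res = minimize(objective, x0, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": ftol, "gtol": 1e-5,
                            "eps": 1e-6})
    xhat = res.x if np.isfinite(res.fun) and res.fun <= ofv0 else x0
    status = "converged" if res.success else "max_iterations" if res.status == 1 else "not_converged"
    theta, omega, sigma = packer.unpack(xhat)
    ofv, eta_full = engine.ofv(theta, omega, sigma, return_etas=True)

    result = FitResult(theta=theta, omega=omega, sigma=sigma, ofv=float(ofv),
                       convergence_status=status,
                       n_subjects=model.n_subjects, n_obs=model.n_obs,
                       n_parameters=xhat.size)

    if compute_ebes:
        result.ebes = pd.DataFrame(
            {"ID": model.subject_ids,
             **{f"eta_{n}": eta_full[:, k] for k, n in enumerate(model.eta_names)}})
        iwres = _iwres(engine, model, theta, omega, sigma, eta_full)
        eta_shr, eps_shr = shrinkage(
            eta_full, omega, eta_names=model.eta_names, iwres=iwres)
        result.eta_shrinkage = eta_shr
        result.eps_shrinkage = eps_shr

    if estimate_rse:
        result.rse = _relative_standard_errors(objective, packer, xhat)
    return result


def _iwres(engine, model, theta, omega, sigma, eta_full) -> np.ndarray:
    cache = model.make_cache(theta)
    ipred = model.predict(theta, cache, eta_full)
    return (model.y - ipred) / np.sqrt(sigma.variance(ipred))


def _relative_standard_errors(objective, packer: _Packer, xhat: np.ndarray,
                              step: float = 1e-4) -> dict[str, float]:
    try:
        hess = _numdiff.hessian(objective, xhat, step=step)
        cov_x = 2.0 * np.linalg.inv(hess)  # OFV = -2 logL => I = H/2
    except np.linalg.LinAlgError:
        warnings.warn("covariance step failed: singular Hessian", stacklevel=2)
        names, _ = packer.natural(xhat)
        return {n: float("nan") for n in names}
    names, nat = packer.natural(xhat)
    jac = np.empty((len(names), xhat.size))
    for i in range(xhat.size):
        h = step * max(1.0, abs(xhat[i]))
        xp, xm = xhat.copy(), xhat.copy()
        xp[i] += h
        xm[i] -= h
        jac[:, i] = (packer.natural(xp)[1] - packer.natural(xm)[1]) / (2 * h)
    var_nat = np.einsum("ij,jk,ik->i", jac, cov_x, jac)
    with np.errstate(invalid="ignore"):
        rse = 100.0 * np.sqrt(np.abs(var_nat)) / np.abs(nat)
        rse[~np.isfinite(rse)] = np.nan
        if (var_nat < -1e-8).any():
            warnings.warn("covariance step produced negative variances",
                          stacklevel=2)
    return {n: float(r) for n, r in zip(names, rse)}


def empirical_bayes(model: NlmeModel, theta: Mapping[str, float],
                    omega: OmegaMatrix, sigma: SigmaParams) -> pd.DataFrame:
    """Per-subject posterior modes of eta at fixed population parameters.

    Subjects without observations sit at the prior mode (eta = 0)."""
    engine = MarginalLikelihood(model, sigma_kind=sigma.kind)
    eta_full, _, _, _, _ = engine.conditional_modes(dict(theta), omega, sigma)
    return pd.DataFrame(
        {"ID": model.subject_ids,
         **{f"eta_{n}": eta_full[:, k] for k, n in enumerate(model.eta_names)}})


def shrinkage(ebes: np.ndarray, omega: OmegaMatrix,
              eta_names: Sequence[str] | None = None,
              iwres: np.ndarray | None = None):
    """Eta and epsilon shrinkage in percent.

    eta-shrinkage: ``100 (1 - SD(EBE_k) / omega_k)`` per random effect;
    undefined (nan) for zero-variance effects.  epsilon-shrinkage:
    ``100 (1 - SD(IWRES))``.
    """
    ebes = np.asarray(ebes, dtype=float)
    if ebes.shape[0] < 2:
        raise ValueError("shrinkage needs at least two subjects")
    if eta_names is None:
        eta_names = omega.names
    out = {}
    for k, name in enumerate(eta_names):
        if name not in omega.names:
            continue
        w2 = omega.matrix[omega.names.index(name), omega.names.index(name)]
        if w2 <= 0:
            out[name] = float("nan")
        else:
            out[name] = float(100.0 * (1.0 - np.std(ebes[:, k], ddof=1) / np.sqrt(w2)))
    eps = float("nan")
    if iwres is not None and np.asarray(iwres).size > 1:
        eps = float(100.0 * (1.0 - np.std(np.asarray(iwres), ddof=1)))
    return out, eps
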