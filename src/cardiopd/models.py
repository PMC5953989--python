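"""Population model definitions for the two biomarker analyses.

A model object binds one biomarker's observations, the relevant dosing
records and subject covariates into flat (stacked) arrays so that the
marginal-likelihood machinery in :mod:`cardiopd.likelihood` can evaluate
predictions and their derivatives for *all* subjects in a handful of
vectorized numpy operations.

Between-subject variability is multiplicative-lognormal: each random-effect
bearing parameter is ``P_i = P_pop * exp(eta_i)``.  Covariate effects are
declared with :class:`CovariateEffect` and add one fixed effect each
(binary/categorical power multipliers, or a power exponent for
median-normalized continuous covariates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import (DOXORUBICIN, EPIRUBICIN, TRASTUZUMAB, LVEF, TROPONIN_T,
                       DoseEvent, ObservationRecord)
from .exposure import TrastuzumabPKParams, effect_conv_term

LN2 = log(2.0)

BINARY_POWER = "binary_power"
CONTINUOUS_POWER = "continuous_power_normalized"
CATEGORICAL_SEPARATE = "categorical_separate"


@dataclass(frozen=True)
class CovariateEffect:
    """One candidate covariate-parameter relationship.

    ``name`` is the fixed-effect name the effect adds to the model's theta
    vector (categorical effects add ``name_<level>`` per non-reference
    level).  ``covariate_name`` is resolved against the coded covariate
    table (see :data:`COVARIATE_SOURCES`) or against externally supplied
    per-subject values (e.g. the predicted troponin-T peak).
    """
    name: str
    target_parameter: str
    form: str
    covariate_name: str
    median: float | None = None        # continuous form only
    levels: tuple = ()                 # categorical: all levels, first = reference

    def __post_init__(self) -> None:
        if self.form not in (BINARY_POWER, CONTINUOUS_POWER, CATEGORICAL_SEPARATE):
            raise ValueError(f"unknown covariate form {self.form!r}")
        if self.form == CONTINUOUS_POWER and (self.median is None or self.median <= 0):
            raise ValueError("continuous covariate needs a positive median")
        if self.form == CATEGORICAL_SEPARATE and len(self.levels) < 2:
            raise ValueError("categorical covariate needs >= 2 levels")

    @property
    def theta_names(self) -> tuple[str, ...]:
        if self.form == CATEGORICAL_SEPARATE:
            return tuple(f"{self.name}_{lvl}" for lvl in self.levels[1:])
        return (self.name,)

    @property
    def degrees_of_freedom(self) -> int:
        return len(self.theta_names)

    @property
    def theta_transforms(self) -> dict[str, str]:
        tr = "identity" if self.form == CONTINUOUS_POWER else "log"
        return {n: tr for n in self.theta_names}

    def start_values(self) -> dict[str, float]:
        return {n: (0.0 if self.form == CONTINUOUS_POWER else 1.0)
                for n in self.theta_names}

    def factors(self, theta: Mapping[str, float], values: np.ndarray) -> np.ndarray:
        """Per-subject multiplier on the target parameter."""
        if self.form == BINARY_POWER:
            return theta[self.name] ** values
        if self.form == CONTINUOUS_POWER:
            return (values / self.median) ** theta[self.name]
        fac = np.ones_like(values, dtype=float)
        for lvl in self.levels[1:]:
            fac = fac * np.where(values == lvl, theta[f"{self.name}_{lvl}"], 1.0)
        return fac


#: covariate name -> column of the coded covariate table
COVARIATE_SOURCES = {
    "age": "AGE",
    "anthracycline_type": "ACTYPE",
    "prior_radiotherapy": "RTX",
    "radiotherapy_laterality": "RTXLAT",
    "hypertension_dx": "HTN",
    "hypertension_status": "HTNSTAT",
    "treatment_arm": "ARM",
    "body_weight": "WT",
    "baseline_lvef": "LVEFBL",
    "ac_to_trastuzumab_gap": "ACGAP",
}


class NlmeModel:
    """Base class: stacked observation arrays plus covariate bookkeeping.

    Subclasses set ``base_theta_names`` and implement ``make_cache``,
    ``predict`` and ``dpred_deta``.
    """

    base_theta_names: tuple[str, ...] = ()
    base_theta_transforms: dict[str, str] = {}

    def __init__(
        self,
        observations: Sequence[ObservationRecord],
        biomarker: str,
        covariates: pd.DataFrame | None = None,
        covariate_effects: Sequence[CovariateEffect] = (),
        etas: tuple[str, ...] = (),
        extra_covariates: Mapping[str, Mapping[str, float]] | None = None,
    ) -> None:
        obs = [o for o in observations if o.biomarker == biomarker]
        self.subject_ids: list[str] = list(dict.fromkeys(o.subject_id for o in obs))
        sidx = {s: i for i, s in enumerate(self.subject_ids)}
        self.n_subjects = len(self.subject_ids)
        self.y = np.array([o.value for o in obs], dtype=float)
        self.obs_times = np.array([o.time for o in obs], dtype=float)
        self.subj_idx = np.array([sidx[o.subject_id] for o in obs], dtype=np.intp)
        self.n_obs = self.y.size
        self.covariate_effects = list(covariate_effects)
        self.eta_names = tuple(etas)
        self._extra = dict(extra_covariates or {})
        self._cov_table = covariates
        self._cov_values = {
            eff.name: self._resolve_covariate(eff) for eff in self.covariate_effects
        }

    # -- theta bookkeeping ------------------------------------------------
    @property
    def theta_names(self) -> tuple[str, ...]:
        names = list(self.base_theta_names)
        for eff in self.covariate_effects:
            names.extend(eff.theta_names)
        return tuple(names)

    @property
    def theta_transforms(self) -> dict[str, str]:
        tr = dict(self.base_theta_transforms)
        for eff in self.covariate_effects:
            tr.update(eff.theta_transforms)
        return tr

    def start_theta(self) -> dict[str, float]:
        start = dict(self.base_start())
        for eff in self.covariate_effects:
            start.update(eff.start_values())
        return start

    def base_start(self) -> dict[str, float]:  # pragma: no cover - abstract
        raise NotImplementedError

    def with_covariates(self, effects: Sequence[CovariateEffect]) -> "NlmeModel":
        """A copy of this model with a different set of covariate effects."""
        raise NotImplementedError

    # -- covariates -------------------------------------------------------
    def _resolve_covariate(self, eff: CovariateEffect) -> np.ndarray:
        if eff.covariate_name in self._extra:
            m = self._extra[eff.covariate_name]
            return np.array([float(m[s]) for s in self.subject_ids])
        col = COVARIATE_SOURCES.get(eff.covariate_name)
        if col is None or self._cov_table is None or col not in self._cov_table:
            raise KeyError(
                f"covariate {eff.covariate_name!r} not available for this model")
        t = self._cov_table.set_index(self._cov_table["ID"].astype(str))
        return np.array([float(t.loc[s, col]) for s in self.subject_ids])

    def _factors(self, theta: Mapping[str, float], param: str) -> np.ndarray:
        fac = np.ones(self.n_subjects)
        for eff in self.covariate_effects:
            if eff.target_parameter == param:
                fac = fac * eff.factors(theta, self._cov_values[eff.name])
        return fac

    # -- interface used by the likelihood engine --------------------------
    def make_cache(self, theta: Mapping[str, float]):  # pragma: no cover
        raise NotImplementedError

    def predict(self, theta, cache, eta: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def dpred_deta(self, theta, cache, eta: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _dose_obs_pairs(doses_by_subject, subject_ids, obs_times, subj_idx):
    """Flatten (observation, earlier dose) pairs for bolus superposition."""
    pair_obs, pair_subj, pair_amt, pair_delta = [], [], [], []
    for j in range(obs_times.size):
        s = subj_idx[j]
        for (td, amt) in doses_by_subject.get(subject_ids[s], ()):
            delta = obs_times[j] - td
            if delta >= 0:
                pair_obs.append(j)
                pair_subj.append(s)
                pair_amt.append(amt)
                pair_delta.append(delta)
    return (np.array(pair_obs, dtype=np.intp), np.array(pair_subj, dtype=np.intp),
            np.array(pair_amt, dtype=float), np.array(pair_delta, dtype=float))


class TroponinModel(NlmeModel):
    """Anthracycline K-PD -> direct-effect troponin T model.

    theta: ``trp0`` (ng/L), ``ke`` (1/day), ``slope`` (1/mg) plus covariate
    effects (by default the anthracycline-type multiplier on SLOPE).  Random
    effects: lognormal BSV on ``trp0`` and ``slope``.
    """

    base_theta_names = ("trp0", "ke", "slope")
    base_theta_transforms = {"trp0": "log", "ke": "log", "slope": "log"}

    def __init__(self, doses: Sequence[DoseEvent],
                 observations: Sequence[ObservationRecord],
                 covariates: pd.DataFrame | None = None,
                 covariate_effects: Sequence[CovariateEffect] = (),
                 etas: tuple[str, ...] = ("trp0", "slope"),
                 extra_covariates=None) -> None:
        super().__init__(observations, TROPONIN_T, covariates,
                         covariate_effects, etas, extra_covariates)
        self._doses = list(doses)
        by_subj: dict[str, list] = {}
        for d in doses:
            if d.drug in (DOXORUBICIN, EPIRUBICIN):
                by_subj.setdefault(d.subject_id, []).append((d.time, d.amount))
        for v in by_subj.values():
            v.sort()
        (self._p_obs, self._p_subj, self._p_amt,
         self._p_delta) = _dose_obs_pairs(by_subj, self.subject_ids,
                                          self.obs_times, self.subj_idx)

    def base_start(self) -> dict[str, float]:
        base = float(np.median(self.y[self.obs_times == 0])) if (self.obs_times == 0).any() else float(np.median(self.y))
        return {"trp0": max(base, 0.5), "ke": 5e-3, "slope": 3e-3}

    def with_covariates(self, effects):
        return TroponinModel(self._doses, _records_from(self), self._cov_table,
                             effects, self.eta_names, self._extra)

    def make_cache(self, theta) -> np.ndarray:
        """Virtual anthracycline amount at each observation (mg)."""
        ke_s = theta["ke"] * self._factors(theta, "ke")
        ke_pair = ke_s[self._p_subj]
        contrib = self._p_amt * np.exp(-ke_pair * self._p_delta)
        return np.bincount(self._p_obs, weights=contrib, minlength=self.n_obs)

    def _subject_params(self, theta, eta):
        b0 = theta["trp0"] * self._factors(theta, "trp0")
        sl = theta["slope"] * self._factors(theta, "slope")
        cols = {n: i for i, n in enumerate(self.eta_names)}
        if "trp0" in cols:
            b0 = b0 * np.exp(eta[:, cols["trp0"]])
        if "slope" in cols:
            sl = sl * np.exp(eta[:, cols["slope"]])
        return b0, sl

    def predict(self, theta, cache, eta):
        b0, sl = self._subject_params(theta, eta)
        return b0[self.subj_idx] * (1.0 + sl[self.subj_idx] * cache)

    def dpred_deta(self, theta, cache, eta):
        b0, sl = self._subject_params(theta, eta)
        out = np.empty((self.n_obs, len(self.eta_names)))
        for k, name in enumerate(self.eta_names):
            if name == "trp0":
                out[:, k] = b0[self.subj_idx] * (1.0 + sl[self.subj_idx] * cache)
            elif name == "slope":
                out[:, k] = b0[self.subj_idx] * sl[self.subj_idx] * cache
            else:
                raise ValueError(f"no eta mapping for {name!r}")
        return out


class LvefModel(NlmeModel):
    """Trastuzumab effect-compartment -> Emax LVEF suppression model.

    theta: ``lvef0`` (fraction), ``t_half_rec`` (days), ``ec50``
    (effect-level units) plus covariate effects (by default the predicted
    troponin-T-peak power on EC50).  Random effects: lognormal BSV on
    ``lvef0`` and ``ec50`` (correlation supported via the omega matrix).
    """

    base_theta_names = ("lvef0", "t_half_rec", "ec50")
    base_theta_transforms = {"lvef0": "log", "t_half_rec": "log", "ec50": "log"}

    def __init__(self, doses: Sequence[DoseEvent],
                 observations: Sequence[ObservationRecord],
                 pk: TrastuzumabPKParams,
                 covariates: pd.DataFrame | None = None,
                 covariate_effects: Sequence[CovariateEffect] = (),
                 etas: tuple[str, ...] = ("lvef0", "ec50"),
                 extra_covariates=None) -> None:
        super().__init__(observations, LVEF, covariates,
                         covariate_effects, etas, extra_covariates)
        self.pk = pk
        self._doses = list(doses)
        coef, lam = pk.bolus_terms()
        by_subj: dict[str, list] = {}
        for d in doses:
            if d.drug == TRASTUZUMAB:
                by_subj.setdefault(d.subject_id, []).append((d.time, d.amount))
        for v in by_subj.values():
            v.sort()
        # pairs expanded over the two disposition exponentials
        p_obs, p_subj, p_amt, p_delta = _dose_obs_pairs(
            by_subj, self.subject_ids, self.obs_times, self.subj_idx)
        n_terms = coef.size
        self._p_obs = np.repeat(p_obs, n_terms)
        self._p_subj = np.repeat(p_subj, n_terms)
        self._p_coef = (p_amt[:, None] * coef[None, :]).ravel()
        self._p_lam = np.tile(lam, p_amt.size)
        self._p_delta = np.repeat(p_delta, n_terms)

    def base_start(self) -> dict[str, float]:
        return {"lvef0": float(np.clip(np.median(self.y), 0.3, 0.8)),
                "t_half_rec": 40.0, "ec50": 1e5}

    def with_covariates(self, effects):
        return LvefModel(self._doses, _records_from(self), self.pk,
                         self._cov_table, effects, self.eta_names, self._extra)

    def make_cache(self, theta) -> np.ndarray:
        """Effect-compartment level at each observation."""
        krec_s = (LN2 / theta["t_half_rec"]) / self._factors(theta, "t_half_rec")
        krec_pair = krec_s[self._p_subj]
        contrib = effect_conv_term(self._p_coef, self._p_lam, krec_pair, self._p_delta)
        return np.bincount(self._p_obs, weights=contrib, minlength=self.n_obs)

    def _subject_params(self, theta, eta):
        l0 = theta["lvef0"] * self._factors(theta, "lvef0")
        e50 = theta["ec50"] * self._factors(theta, "ec50")
        cols = {n: i for i, n in enumerate(self.eta_names)}
        if "lvef0" in cols:
            l0 = l0 * np.exp(eta[:, cols["lvef0"]])
        if "ec50" in cols:
            e50 = e50 * np.exp(eta[:, cols["ec50"]])
        return l0, e50

    def predict(self, theta, cache, eta):
        l0, e50 = self._subject_params(theta, eta)
        denom = cache + e50[self.subj_idx]
        return l0[self.subj_idx] * (1.0 - cache / denom)

    def dpred_deta(self, theta, cache, eta):
        l0, e50 = self._subject_params(theta, eta)
        es = e50[self.subj_idx]
        denom = cache + es
        out = np.empty((self.n_obs, len(self.eta_names)))
        for k, name in enumerate(self.eta_names):
            if name == "lvef0":
                out[:, k] = l0[self.subj_idx] * (1.0 - cache / denom)
            elif name == "ec50":
                out[:, k] = l0[self.subj_idx] * cache * es / denom ** 2
            else:
                raise ValueError(f"no eta mapping for {name!r}")
        return out


class ConstantMeanModel(NlmeModel):
    """Toy model ``f_ij = mu + eta_i`` (additive random effect).

    With additive residual error the marginal likelihood is Gaussian in
    closed form, which makes this the exactness oracle for the Laplace
    approximation.
    """

    base_theta_names = ("mu",)
    base_theta_transforms = {"mu": "identity"}

    def __init__(self, observations, biomarker=TROPONIN_T) -> None:
        super().__init__(observations, biomarker, etas=("mu",))

    def base_start(self):
        return {"mu": float(np.mean(self.y))}

    def make_cache(self, theta):
        return None

    def predict(self, theta, cache, eta):
        return theta["mu"] + eta[self.subj_idx, 0]

    def dpred_deta(self, theta, cache, eta):
        return np.ones((self.n_obs, 1))


def _records_from(model: NlmeModel) -> list[ObservationRecord]:
    """Reconstruct observation records from the stacked arrays."""
    biomarker = {TroponinModel: TROPONIN_T, LvefModel: LVEF}.get(type(model), TROPONIN_T)
    return [ObservationRecord(model.subject_ids[s], t, biomarker, v)
            for s, t, v in zip(model.subj_idx, model.obs_times, model.y)]
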