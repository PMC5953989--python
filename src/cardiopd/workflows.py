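"""Sequential analysis workflows tying the modules together.

The two biomarker models are estimated sequentially, not simultaneously:
the troponin model is fitted first, per-subject troponin-T peaks are
predicted from its empirical Bayes estimates, and those peaks then enter
the LVEF model as a fixed subject-level covariate on EC50.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .covariates import forward_backward
from .datasets import (DOXORUBICIN, EPIRUBICIN, TRASTUZUMAB, DoseEvent,
                       ObservationRecord)
from .exposure import KPDParams, TrastuzumabPKParams, DEFAULT_TRASTUZUMAB_PK
from .fitting import FitResult, fit
from .likelihood import OmegaMatrix, SigmaParams
from .models import (CONTINUOUS_POWER, BINARY_POWER, CovariateEffect,
                     LvefModel, TroponinModel)
from .structural import TroponinParams, predicted_trpmax, predicted_trp_day21


def troponin_model(doses, observations, covariates,
                   include_type_effect: bool = True,
                   etas=("trp0", "slope")) -> TroponinModel:
    effects = []
    if include_type_effect:
        effects.append(CovariateEffect("type_effect", "slope", BINARY_POWER,
                                       "anthracycline_type"))
    return TroponinModel(doses, observations, covariates, effects, etas=etas)


def fit_troponin(doses, observations, covariates,
                 include_type_effect: bool = True,
                 **fit_kwargs) -> FitResult:
    """Fit the anthracycline K-PD / direct-effect troponin model."""
    model = troponin_model(doses, observations, covariates, include_type_effect)
    return fit(model, **fit_kwargs)


def trpmax_from_fit(result: FitResult,
                    doses: Sequence[DoseEvent],
                    covariates: pd.DataFrame,
                    day21: bool = False) -> dict[str, float]:
    """Per-subject predicted troponin-T peaks from the EBEs of a fit.

    Individual TRP0 and SLOPE are the population estimates scaled by
    ``exp(eta)``; the peak is evaluated just after the subject's last
    anthracycline dose (or 21 days later with ``day21=True``).
    """
    theta = result.theta
    kpd = KPDParams(ke=theta["ke"])
    type_effect = theta.get("type_effect", 1.0)
    cov = covariates.set_index(covariates["ID"].astype(str))
    ebes = (result.ebes.set_index("ID") if result.ebes is not None
            else pd.DataFrame())
    by_subject: dict[str, list[DoseEvent]] = {}
    for d in doses:
        if d.drug in (DOXORUBICIN, EPIRUBICIN):
            by_subject.setdefault(d.subject_id, []).append(d)
    out: dict[str, float] = {}
    predictor = predicted_trp_day21 if day21 else predicted_trpmax
    for sid, subj_doses in by_subject.items():
        eta_trp0 = float(ebes.loc[sid, "eta_trp0"]) if sid in ebes.index else 0.0
        eta_slope = float(ebes.loc[sid, "eta_slope"]) if sid in ebes.index else 0.0
        params = TroponinParams(trp0=theta["trp0"] * np.exp(eta_trp0),
                                slope=theta["slope"] * np.exp(eta_slope),
                                type_effect=type_effect)
        ac_type = (DOXORUBICIN if int(cov.loc[sid, "ACTYPE"]) == 0
                   else EPIRUBICIN) if sid in cov.index else DOXORUBICIN
        out[sid] = predictor(sorted(subj_doses, key=lambda d: d.time),
                             params, kpd, ac_type)
    return out


def lvef_model(doses, observations, covariates, trpmax: Mapping[str, float],
               pk: TrastuzumabPKParams | None = None,
               include_trpmax_covariate: bool = True,
               trpmax_median: float = 18.0,
               etas=("lvef0", "ec50")) -> LvefModel:
    effects = []
    if include_trpmax_covariate:
        effects.append(CovariateEffect("trpmax_exponent", "ec50",
                                       CONTINUOUS_POWER, "trpmax",
                                       median=trpmax_median))
    return LvefModel(doses, observations, pk or DEFAULT_TRASTUZUMAB_PK,
                     covariates, effects, etas=etas,
                     extra_covariates={"trpmax": dict(trpmax)})


def fit_lvef(doses, observations, covariates, trpmax: Mapping[str, float],
             pk: TrastuzumabPKParams | None = None,
             include_trpmax_covariate: bool = True,
             start_omega: OmegaMatrix | None = None,
             **fit_kwargs) -> FitResult:
    """Fit the trastuzumab effect-compartment / Emax LVEF model."""
    model = lvef_model(doses, observations, covariates, trpmax, pk,
                       include_trpmax_covariate)
    if start_omega is None:
        # correlated baseline/sensitivity random effects by default
        start_omega = OmegaMatrix.from_cv(("lvef0", "ec50"), [10.0, 50.0],
                                          correlations={("lvef0", "ec50"): 0.0})
    return fit(model, start_omega=start_omega, **fit_kwargs)


def sequential_analysis(doses, observations, covariates,
                        pk: TrastuzumabPKParams | None = None,
                        **fit_kwargs):
    """Full sequential pipeline: troponin fit -> EBE peaks -> LVEF fit.

    Returns (troponin FitResult, trpmax dict, LVEF FitResult).
    """
    trp_fit = fit_troponin(doses, observations, covariates, **fit_kwargs)
    trpmax = trpmax_from_fit(trp_fit, doses, covariates)
    lv_fit = fit_lvef(doses, observations, covariates, trpmax, pk, **fit_kwargs)
    return trp_fit, trpmax, lv_fit


def covariate_search(model_builder, candidates, alpha_fwd=0.01,
                     alpha_bwd=0.005, **fit_kwargs):
    """Run forward/backward selection where ``model_builder(effects)``
    returns a fresh model containing exactly the given covariate effects."""

    def fit_subset(included):
        return fit(model_builder(list(included)), estimate_rse=False,
                   compute_ebes=False, **fit_kwargs)

    return forward_backward(fit_subset, candidates,
                            alpha_fwd=alpha_fwd, alpha_bwd=alpha_bwd)
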