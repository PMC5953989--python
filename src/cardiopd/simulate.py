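"""Synthetic trial generator emulating the cardiac-safety study design.

The generator reproduces the design of a 206-patient HER2-positive early
breast cancer cohort: 2–6 anthracycline cycles (doxorubicin or epirubicin)
every 21 days, a gap (median 21 days), then 52 weeks of trastuzumab on
either a weekly (4 mg/kg loading, 2 mg/kg maintenance) or a 3-weekly
(8 -> 6 mg/kg) schedule.  Troponin T and NT-proBNP are sampled before
anthracyclines, before trastuzumab and at weeks 3, 12, 24, 36, 52, 64, 78
and 92 after trastuzumab start; LVEF at the same visits minus weeks 3 and
64.  Biomarker values are generated from the structural models with
lognormal between-subject variability, proportional residual error and
LLOQ/2 substitution below the assay limits; NT-proBNP is emitted as
exposure-independent lognormal noise (format fidelity only).

All randomness flows from one master seed through per-subject substreams,
so a subject's data do not change when the cohort size does.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import (DOXORUBICIN, EPIRUBICIN, LVEF, NTPROBNP, TRASTUZUMAB,
                       TROPONIN_T, DoseEvent, ObservationRecord,
                       SubjectCovariates, apply_lloq_rule, covariates_to_frame)
from .diagnostics import classify_lvef_decline
from .exposure import (DEFAULT_TRASTUZUMAB_PK, EffectCompartmentParams,
                       KPDParams, TrastuzumabPKParams,
                       effect_compartment_level)
from .likelihood import OmegaMatrix, SigmaParams
from .structural import (LvefParams, TroponinParams, lvef_prediction,
                         predicted_trpmax, troponin_prediction)
from .exposure import anthracycline_amount

WEEK = 7.0

TROPONIN_WEEKS = (3, 12, 24, 36, 52, 64, 78, 92)
LVEF_WEEKS = (12, 24, 36, 52, 78, 92)


@dataclass
class TrialDesign:
    """Study design; defaults follow the reported cohort characteristics."""
    n_subjects: int = 206
    p_doxorubicin: float = 181 / 206              # 87.9%
    cycle_counts: tuple[int, ...] = (2, 3, 4, 5, 6)
    cycle_probs: tuple[float, ...] = (0.08, 0.17, 0.40, 0.20, 0.15)  # median 4
    cycle_interval: float = 21.0                  # days
    dox_dose: tuple[float, float, float] = (75.0, 110.0, 150.0)   # min, mode, max (mg)
    epi_dose: tuple[float, float, float] = (100.0, 170.0, 200.0)
    p_weekly_trastuzumab: float = 144 / 206
    trastuzumab_weeks: int = 52
    # mg/kg: (loading, maintenance)
    weekly_doses: tuple[float, float] = (4.0, 2.0)
    threeweekly_doses: tuple[float, float] = (8.0, 6.0)
    first_dose_day: float = 1.0   # baseline samples precede the first dose
    gap_range: tuple[float, float, float] = (14.0, 21.0, 30.0)  # triangular core
    p_long_gap: float = 0.06
    long_gap_max: float = 217.0
    body_weight: tuple[float, float, float] = (50.0, 70.0, 100.0)  # kg
    age_range: tuple[float, float, float] = (25.0, 50.0, 69.0)
    p_radiotherapy: float = 112 / 206
    p_left_given_rtx: float = 58 / 112
    p_hypertension: float = 24 / 206
    htn_status_probs: tuple[float, float, float] = (5 / 24, 12 / 24, 7 / 24)  # past, dormant, active
    p_candesartan: float = 0.5
    ntprobnp_baseline_median: float = 70.0        # pg/mL
    ntprobnp_baseline_cv: float = 1.0             # lognormal sdlog
    ntprobnp_noise_cv: float = 0.5
    lloq: Mapping[str, float] = field(
        default_factory=lambda: {TROPONIN_T: 3.0, NTPROBNP: 5.0})

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if abs(sum(self.cycle_probs) - 1.0) > 1e-9:
            raise ValueError("cycle probabilities must sum to 1")
        if not 0 <= self.p_doxorubicin <= 1:
            raise ValueError("p_doxorubicin must be a probability")


@dataclass
class TruthParameters:
    """Simulation truth: fixed effects, BSV and residual error of both models."""
    troponin: TroponinParams
    kpd: KPDParams
    troponin_omega: OmegaMatrix
    troponin_sigma: SigmaParams
    lvef: LvefParams
    effect: EffectCompartmentParams
    lvef_omega: OmegaMatrix
    lvef_sigma: SigmaParams
    pk: TrastuzumabPKParams = field(default_factory=lambda: DEFAULT_TRASTUZUMAB_PK)

    @classmethod
    def published_estimates(cls, pk: TrastuzumabPKParams | None = None) -> "TruthParameters":
        """The reported final-model estimates as simulation truth."""
        return cls(
            troponin=TroponinParams(trp0=4.7, slope=8.84e-3, type_effect=0.524),
            kpd=KPDParams(ke=8.49e-3),
            troponin_omega=OmegaMatrix.from_cv(("trp0", "slope"), [39.2, 57.7]),
            troponin_sigma=SigmaParams(sd=0.301),
            lvef=LvefParams(lvef0=0.599, ec50=2.18e5, trpmax_exponent=-1.16),
            effect=EffectCompartmentParams(t_half_rec=67.9),
            lvef_omega=OmegaMatrix.from_cv(
                ("lvef0", "ec50"), [7.07, 82.9],
                correlations={("lvef0", "ec50"): 0.585}),
            lvef_sigma=SigmaParams(sd=0.078),
            pk=pk or DEFAULT_TRASTUZUMAB_PK,
        )


@dataclass
class SimulatedTrial:
    doses: list[DoseEvent]
    observations: list[ObservationRecord]
    covariates: list[SubjectCovariates]
    latent: pd.DataFrame   # per-subject etas, individual parameters, TRP_max

    @property
    def covariates_frame(self) -> pd.DataFrame:
        return covariates_to_frame(self.covariates)


def _psd_factor(matrix: np.ndarray) -> np.ndarray:
    """Square root of a PSD matrix that is exact for zero rows/columns."""
    try:
        return np.linalg.cholesky(matrix)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(matrix)
        return vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))


def _triangular(rng, lo_mode_hi):
    lo, mode, hi = lo_mode_hi
    return float(rng.triangular(lo, mode, hi))


def simulate_trial(design: TrialDesign | None = None,
                   truth: TruthParameters | None = None,
                   seed: int = 0) -> SimulatedTrial:
    """Generate one synthetic trial dataset plus its latent truth table."""
    design = design or TrialDesign()
    truth = truth or TruthParameters.published_estimates()

    streams = np.random.SeedSequence(seed).spawn(design.n_subjects)
    doses: list[DoseEvent] = []
    observations: list[ObservationRecord] = []
    covariates: list[SubjectCovariates] = []
    latent_rows = []

    chol_trp = _psd_factor(truth.troponin_omega.matrix)
    chol_lvef = _psd_factor(truth.lvef_omega.matrix)

    for s, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        sid = f"S{s + 1:04d}"

        # ---- covariates & schedule -----------------------------------
        ac_type = DOXORUBICIN if rng.random() < design.p_doxorubicin else EPIRUBICIN
        n_cycles = int(rng.choice(design.cycle_counts, p=design.cycle_probs))
        weight = _triangular(rng, design.body_weight)
        rtx = rng.random() < design.p_radiotherapy
        laterality = ("left" if rng.random() < design.p_left_given_rtx else "right") if rtx else "none"
        htn = rng.random() < design.p_hypertension
        htn_status = (str(rng.choice(("past", "dormant", "active"),
                                     p=design.htn_status_probs)) if htn else "none")
        arm = "candesartan" if rng.random() < design.p_candesartan else "placebo"
        age = _triangular(rng, design.age_range)
        if rng.random() < design.p_long_gap:
            gap = float(rng.uniform(design.gap_range[2], design.long_gap_max))
        else:
            gap = _triangular(rng, design.gap_range)

        ac_times = design.first_dose_day + np.arange(n_cycles) * design.cycle_interval
        dose_range = design.dox_dose if ac_type == DOXORUBICIN else design.epi_dose
        ac_amounts = [_triangular(rng, dose_range) for _ in range(n_cycles)]
        subj_doses = [DoseEvent(sid, float(t), ac_type, a)
                      for t, a in zip(ac_times, ac_amounts)]

        t_start = float(ac_times[-1] + gap)  # first trastuzumab dose
        weekly = rng.random() < design.p_weekly_trastuzumab
        if weekly:
            load, maint = design.weekly_doses
            tr_times = t_start + WEEK * np.arange(design.trastuzumab_weeks)
        else:
            load, maint = design.threeweekly_doses
            tr_times = t_start + 3 * WEEK * np.arange(
                int(np.ceil(design.trastuzumab_weeks / 3)))
        tr_amounts = [load * weight] + [maint * weight] * (len(tr_times) - 1)
        subj_doses += [DoseEvent(sid, float(t), TRASTUZUMAB, a)
                       for t, a in zip(tr_times, tr_amounts)]

        # ---- latent individual parameters ----------------------------
        eta_trp = chol_trp @ rng.standard_normal(2)   # (trp0, slope)
        eta_lv = chol_lvef @ rng.standard_normal(2)   # (lvef0, ec50)
        trp0_i = truth.troponin.trp0 * np.exp(eta_trp[0])
        slope_i = truth.troponin.slope * np.exp(eta_trp[1])
        trp_params_i = TroponinParams(trp0=trp0_i, slope=slope_i,
                                      type_effect=truth.troponin.type_effect)
        trp_max_i = predicted_trpmax([d for d in subj_doses if d.drug != TRASTUZUMAB],
                                     trp_params_i, truth.kpd, ac_type)
        lvef0_i = truth.lvef.lvef0 * np.exp(eta_lv[0])
        ec50_pop_i = truth.lvef.ec50 * np.exp(eta_lv[1])
        lvef_params_i = LvefParams(lvef0=min(lvef0_i, 0.999), ec50=ec50_pop_i,
                                   trpmax_exponent=truth.lvef.trpmax_exponent,
                                   trpmax_median=truth.lvef.trpmax_median)

        # ---- observation times ---------------------------------------
        t_trp = np.array([0.0, t_start, *(t_start + WEEK * np.array(TROPONIN_WEEKS))])
        t_lvef = np.array([0.0, t_start, *(t_start + WEEK * np.array(LVEF_WEEKS))])

        ant_doses = [d for d in subj_doses if d.drug != TRASTUZUMAB]
        tra_doses = [d for d in subj_doses if d.drug == TRASTUZUMAB]

        a_ant = anthracycline_amount(ant_doses, truth.kpd, t_trp)
        trp_pred = troponin_prediction(a_ant, trp_params_i, ac_type)
        trp_obs = trp_pred * (1.0 + truth.troponin_sigma.sd
                              * rng.standard_normal(t_trp.size))

        c_eff = effect_compartment_level(tra_doses, truth.pk, truth.effect, t_lvef)
        lvef_pred = lvef_prediction(c_eff, lvef_params_i, trp_max_i)
        lvef_obs = lvef_pred * (1.0 + truth.lvef_sigma.sd
                                * rng.standard_normal(t_lvef.size))

        bnp_base = design.ntprobnp_baseline_median * np.exp(
            design.ntprobnp_baseline_cv * rng.standard_normal())
        bnp_obs = bnp_base * np.exp(design.ntprobnp_noise_cv
                                    * rng.standard_normal(t_trp.size))

        subj_obs = []
        for t, v in zip(t_trp, trp_obs):
            subj_obs.append(ObservationRecord(sid, float(t), TROPONIN_T,
                                              float(max(v, 1e-6))))
        for t, v in zip(t_lvef, lvef_obs):
            subj_obs.append(ObservationRecord(sid, float(t), LVEF,
                                              float(np.clip(v, 1e-6, 1.0))))
        for t, v in zip(t_trp, bnp_obs):
            subj_obs.append(ObservationRecord(sid, float(t), NTPROBNP,
                                              float(max(v, 1e-6))))
        subj_obs.sort(key=lambda o: o.time)
        subj_obs = apply_lloq_rule(subj_obs, design.lloq)

        doses.extend(subj_doses)
        observations.extend(subj_obs)
        covariates.append(SubjectCovariates(
            subject_id=sid, age=age, anthracycline_type=ac_type,
            prior_radiotherapy=rtx, radiotherapy_laterality=laterality,
            hypertension_dx=htn, hypertension_status=htn_status,
            treatment_arm=arm, body_weight=weight,
            baseline_lvef_pre_trastuzumab=float(lvef_pred[1]),
            ac_to_trastuzumab_gap=gap))
        latent_rows.append({
            "ID": sid, "eta_trp0": eta_trp[0], "eta_slope": eta_trp[1],
            "eta_lvef0": eta_lv[0], "eta_ec50": eta_lv[1],
            "trp0_i": trp0_i, "slope_i": slope_i, "lvef0_i": lvef0_i,
            "ec50_pop_i": ec50_pop_i, "trp_max": trp_max_i,
            "t_trastuzumab_start": t_start,
            "cumulative_anthracycline_mg": float(sum(ac_amounts)),
        })

    return SimulatedTrial(doses=doses, observations=observations,
                          covariates=covariates,
                          latent=pd.DataFrame(latent_rows))


def simulate_dropout(trial: SimulatedTrial, enabled: bool = True,
                     lvef_floor: float = 0.45,
                     drop_from_baseline: float = 0.15) -> SimulatedTrial:
    """Informative dropout: once a subject's observed LVEF meets the
    clinically-relevant-decline rule, later trastuzumab doses and LVEF
    records are removed (mimicking treatment discontinuation)."""
    if not enabled:
        return trial
    cutoff: dict[str, float] = {}
    for cov in trial.covariates:
        sid = cov.subject_id
        series = sorted((o for o in trial.observations
                         if o.subject_id == sid and o.biomarker == LVEF),
                        key=lambda o: o.time)
        if len(series) < 2:
            continue
        baseline = series[0].value
        for o in series[1:]:
            if classify_lvef_decline(baseline, [o.value],
                                     floor=lvef_floor,
                                     drop=drop_from_baseline):
                cutoff[sid] = o.time
                break
    if not cutoff:
        return trial
    doses = [d for d in trial.doses
             if not (d.drug == TRASTUZUMAB and d.time > cutoff.get(d.subject_id, np.inf))]
    observations = [o for o in trial.observations
                    if not (o.biomarker == LVEF and o.time > cutoff.get(o.subject_id, np.inf))]
    return SimulatedTrial(doses=doses, observations=observations,
                          covariates=trial.covariates, latent=trial.latent)
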