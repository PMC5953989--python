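"""Per-subject drug exposure over time.

Three layers feed the biomarker models:

* a K-PD virtual compartment for the anthracyclines — dose amounts enter as
  boluses and decay mono-exponentially (``dA/dt = -ke * A``); the "exposure"
  is the remaining amount in mg, not a concentration;
* a linear two-compartment disposition model for trastuzumab with fixed
  population parameters (clearance CL, central volume V1, intercompartmental
  clearance Q, peripheral volume V2), evaluated by analytic bi-exponential
  superposition;
* an effect compartment integrating the trastuzumab concentration with
  first-order loss at the recovery rate constant ``k_rec = ln 2 / t_half_rec``
  (``dCeff/dt = C_trast - k_rec * Ceff``), evaluated by exact per-term
  convolution.  Ceff therefore carries concentration x time units (mg/L x day)
  and is the quantity the LVEF EC50 is expressed against.

All times are days.  Dose inputs are bolus by default; trastuzumab supports
an optional zero-order infusion mode for the plasma concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from typing import Callable, Sequence

import numpy as np

from .datasets import DoseEvent

LN2 = log(2.0)


@dataclass
class KPDParams:
    """Virtual anthracycline compartment: first-order elimination rate (1/day)."""
    ke: float

    def __post_init__(self) -> None:
        if self.ke <= 0:
            raise ValueError("ke must be > 0")

    @property
    def half_life(self) -> float:
        return LN2 / self.ke


@dataclass
class TrastuzumabPKParams:
    """Fixed-effect two-compartment disposition parameters (L/day and L)."""
    clearance: float
    central_volume: float
    intercompartmental_clearance: float
    peripheral_volume: float

    def __post_init__(self) -> None:
        for name in ("clearance", "central_volume",
                     "intercompartmental_clearance", "peripheral_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def micro_constants(self) -> tuple[float, float, float]:
        """(k10, k12, k21) in 1/day."""
        k10 = self.clearance / self.central_volume
        k12 = self.intercompartmental_clearance / self.central_volume
        k21 = self.intercompartmental_clearance / self.peripheral_volume
        return k10, k12, k21

    @property
    def hybrid_constants(self) -> tuple[float, float]:
        """Fast and slow disposition rate constants (alpha, beta)."""
        k10, k12, k21 = self.micro_constants
        s = k10 + k12 + k21
        p = k10 * k21
        disc = np.sqrt(s * s - 4.0 * p)
        alpha = 0.5 * (s + disc)
        beta = 0.5 * (s - disc)
        return alpha, beta

    def bolus_terms(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit-bolus central concentration ``C(t) = sum c_k exp(-lam_k t)``.

        Returns (coefficients per mg, rates); coefficients sum to 1/V1.
        """
        k10, k12, k21 = self.micro_constants
        alpha, beta = self.hybrid_constants
        a = (alpha - k21) / (alpha - beta) / self.central_volume
        b = (k21 - beta) / (alpha - beta) / self.central_volume
        return np.array([a, b]), np.array([alpha, beta])


#: Literature-typical two-compartment disposition for a therapeutic IgG1
#: antibody such as trastuzumab.  These are configuration defaults, not
#: estimates of this package; any analysis should supply the values of the
#: population PK model it intends to reproduce (config section
#: ``pk_parameters``).
DEFAULT_TRASTUZUMAB_PK = TrastuzumabPKParams(
    clearance=0.225,                  # L/day
    central_volume=2.95,              # L
    intercompartmental_clearance=0.69,  # L/day
    peripheral_volume=2.68,           # L
)


@dataclass
class EffectCompartmentParams:
    """Recovery half-life of trastuzumab-induced cardiac damage (days)."""
    t_half_rec: float

    def __post_init__(self) -> None:
        if self.t_half_rec <= 0:
            raise ValueError("t_half_rec must be > 0")

    @property
    def k_rec(self) -> float:
        return LN2 / self.t_half_rec


def _check_sorted(doses: Sequence[DoseEvent]) -> None:
    times = [d.time for d in doses]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("doses must be sorted by time")


def anthracycline_amount(doses: Sequence[DoseEvent], params: KPDParams, t):
    """K-PD virtual amount A(t) in mg by bolus superposition.

    ``A(t) = sum_{t_d <= t} amount_d * exp(-ke (t - t_d))``; vectorized over
    ``t`` (scalar in, scalar out).
    """
    _check_sorted(doses)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t_arr)
    for d in doses:
        tau = t_arr - d.time
        mask = tau >= 0
        out[mask] += d.amount * np.exp(-params.ke * tau[mask])
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def trastuzumab_concentration(
    doses: Sequence[DoseEvent],
    params: TrastuzumabPKParams,
    t,
    infusion: bool = False,
):
    """Central-compartment trastuzumab concentration (mg/L).

    Bolus superposition of the analytic bi-exponential unit response; with
    ``infusion=True``, doses with a positive ``infusion_duration`` enter as
    zero-order infusions (exact piecewise solution).
    """
    _check_sorted(doses)
    coef, lam = params.bolus_terms()
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t_arr)
    for d in doses:
        tau = t_arr - d.time
        mask = tau >= 0
        if not mask.any():
            continue
        tm = tau[mask]
        if infusion and d.infusion_duration > 0:
            dur = d.infusion_duration
            rate = d.amount / dur
            c = np.zeros_like(tm)
            for ck, lk in zip(coef, lam):
                te = np.minimum(tm, dur)
                # during infusion: rate*ck/lk*(1-e^{-lk t}); after: decay from end
                c += rate * ck / lk * (1.0 - np.exp(-lk * te)) * np.exp(
                    -lk * np.maximum(tm - dur, 0.0))
            out[mask] += c
        else:
            out[mask] += d.amount * (coef * np.exp(-np.outer(tm, lam))).sum(axis=1)
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def effect_conv_term(coef, lam, k_rec: float, tau):
    """Convolution of ``coef * exp(-lam s)`` input with ``exp(-k_rec (t-s))``.

    Returns ``coef * (exp(-lam tau) - exp(-k_rec tau)) / (k_rec - lam)`` with
    the removable singularity at ``lam == k_rec`` handled analytically
    (limit ``coef * tau * exp(-k_rec tau)``).
    """
    tau = np.asarray(tau, dtype=float)
    lam = np.asarray(lam, dtype=float)
    coef = np.asarray(coef, dtype=float)
    k_rec = np.asarray(k_rec, dtype=float)
    diff = k_rec - lam
    near = np.abs(diff) < 1e-12 * np.maximum(k_rec, 1e-30)
    safe = np.where(near, 1.0, diff)
    out = coef * (np.exp(-lam * tau) - np.exp(-k_rec * tau)) / safe
    lim = coef * tau * np.exp(-k_rec * tau)
    return np.where(near, lim, out)


def effect_compartment_level(
    doses: Sequence[DoseEvent],
    pk: TrastuzumabPKParams,
    params: EffectCompartmentParams,
    t,
):
    """Effect-compartment level Ceff(t) for a bolus trastuzumab schedule.

    Exact integral of ``dCeff/dt = C_trast - k_rec Ceff`` with ``Ceff(0)=0``,
    computed term-by-term over the bi-exponential unit responses.
    """
    _check_sorted(doses)
    coef, lam = pk.bolus_terms()
    k_rec = params.k_rec
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t_arr)
    for d in doses:
        tau = t_arr - d.time
        mask = tau >= 0
        if not mask.any():
            continue
        tm = tau[mask]
        acc = np.zeros_like(tm)
        for ck, lk in zip(coef, lam):
            acc += effect_conv_term(d.amount * ck, lk, k_rec, tm)
        out[mask] += acc
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


@dataclass
class ExposureProfile:
    """Callable per-subject exposure: time -> (A_ant, C_trast, C_eff)."""
    subject_id: str
    evaluator: Callable[[float], tuple[float, float, float]]

    def __call__(self, t):
        return self.evaluator(t)


def exposure_profile(
    subject_id: str,
    doses: Sequence[DoseEvent],
    kpd: KPDParams,
    pk: TrastuzumabPKParams,
    effect: EffectCompartmentParams,
) -> ExposureProfile:
    """Bundle the three exposure curves for one subject's dosing record."""
    ant = sorted((d for d in doses if d.drug != "trastuzumab"), key=lambda d: d.time)
    tra = sorted((d for d in doses if d.drug == "trastuzumab"), key=lambda d: d.time)

    def evaluate(t):
        return (
            anthracycline_amount(ant, kpd, t),
            trastuzumab_concentration(tra, pk, t),
            effect_compartment_level(tra, pk, effect, t),
        )

    return ExposureProfile(subject_id=subject_id, evaluator=evaluate)
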