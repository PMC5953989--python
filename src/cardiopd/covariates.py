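"""Stepwise covariate selection by likelihood-ratio OFV changes.

Forward inclusion adds, one candidate at a time, the covariate giving the
largest OFV drop exceeding the chi-squared threshold at ``alpha_fwd``
(default p < 0.01, 6.63 for 1 df); backward elimination then removes any
retained covariate whose deletion raises the OFV by no more than the
stricter threshold at ``alpha_bwd`` (default p < 0.005, 7.88 for 1 df).
Categorical covariates estimating a separate parameter per level consume
(levels - 1) degrees of freedom and get the correspondingly larger
chi-squared threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import pandas as pd
from scipy.stats import chi2

from .fitting import FitResult
from .models import (BINARY_POWER, CATEGORICAL_SEPARATE, CONTINUOUS_POWER,
                     CovariateEffect)

CovariateCandidate = CovariateEffect  # a candidate is a declared effect


def lrt_threshold(alpha: float, df: int = 1) -> float:
    """Chi-squared upper-``alpha`` quantile: the OFV change that is
    significant at level ``alpha`` with ``df`` degrees of freedom."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(chi2.ppf(1.0 - alpha, df))


@dataclass
class SearchStep:
    phase: str                       # "forward" | "backward"
    candidate: str                   # candidate name
    ofv: float                       # OFV of the model evaluated this step
    delta_ofv: float                 # improvement vs the comparison model
    decision: str                    # "included" | "rejected" | "removed" | "retained"


@dataclass
class SearchTrace:
    steps: list[SearchStep]
    included: tuple[CovariateCandidate, ...]
    final_fit: FitResult
    base_ofv: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"step": i, "phase": s.phase, "candidate": s.candidate,
                              "ofv": s.ofv, "delta_ofv": s.delta_ofv,
                              "decision": s.decision}
                             for i, s in enumerate(self.steps)])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def forward_backward(
    fit_subset: Callable[[tuple[CovariateCandidate, ...]], FitResult],
    candidates: Sequence[CovariateCandidate],
    alpha_fwd: float = 0.01,
    alpha_bwd: float = 0.005,
) -> SearchTrace:
    """Greedy forward-inclusion / backward-elimination search.

    ``fit_subset`` fits the model containing exactly the given candidates
    (candidates are passed in their original list order).  Candidate fits
    that raise are skipped with a warning.  Ties break deterministically in
    candidate list order.
    """
    candidates = list(candidates)
    steps: list[SearchStep] = []
    cache: dict[tuple[str, ...], FitResult] = {}

    def fitted(included: list[CovariateCandidate]) -> FitResult:
        inc = tuple(c for c in candidates if c in included)
        key = tuple(c.name for c in inc)
        if key not in cache:
            cache[key] = fit_subset(inc)
        return cache[key]

    base = fitted([])
    included: list[CovariateCandidate] = []
    current_ofv = base.ofv

    # forward inclusion
    while True:
        best = None
        for cand in candidates:
            if cand in included:
                continue
            try:
                trial = fitted(included + [cand])
            except Exception as exc:  # noqa: BLE001 - candidate-level robustness
                warnings.warn(f"fit failed for candidate {cand.name!r}: {exc}",
                              stacklevel=2)
                continue
            drop = current_ofv - trial.ofv
            threshold = lrt_threshold(alpha_fwd, cand.degrees_of_freedom)
            significant = drop > threshold
            steps.append(SearchStep("forward", cand.name, trial.ofv, drop,
                                    "candidate" if significant else "rejected"))
            if significant and (best is None or drop > best[0]):
                best = (drop, cand, trial)
        if best is None:
            break
        _, cand, trial = best
        included.append(cand)
        current_ofv = trial.ofv
        steps.append(SearchStep("forward", cand.name, trial.ofv,
                                best[0], "included"))

    # backward elimination
    changed = True
    while changed and included:
        changed = False
        weakest = None
        for cand in included:
            reduced = fitted([c for c in included if c is not cand])
            increase = reduced.ofv - current_ofv
            threshold = lrt_threshold(alpha_bwd, cand.degrees_of_freedom)
            keeps = increase > threshold
            steps.append(SearchStep("backward", cand.name, reduced.ofv,
                                    increase, "retained" if keeps else "removable"))
            if not keeps and (weakest is None or increase < weakest[0]):
                weakest = (increase, cand, reduced)
        if weakest is not None:
            _, cand, reduced = weakest
            included.remove(cand)
            current_ofv = reduced.ofv
            steps.append(SearchStep("backward", cand.name, reduced.ofv,
                                    weakest[0], "removed"))
            changed = True

    final = fitted(included)
    return SearchTrace(steps=steps, included=tuple(included),
                       final_fit=final, base_ofv=base.ofv)


def default_troponin_candidates() -> list[CovariateCandidate]:
    """Candidate covariate-parameter pairs for the troponin model."""
    return [
        CovariateEffect("type_effect", "slope", BINARY_POWER, "anthracycline_type"),
        CovariateEffect("age_slope", "slope", CONTINUOUS_POWER, "age", median=50.0),
        CovariateEffect("htn_slope", "slope", BINARY_POWER, "hypertension_dx"),
        CovariateEffect("rtx_slope", "slope", BINARY_POWER, "prior_radiotherapy"),
        CovariateEffect("rtxlat_slope", "slope", CATEGORICAL_SEPARATE,
                        "radiotherapy_laterality", levels=(0, 1, 2)),
        CovariateEffect("htnstat_slope", "slope", CATEGORICAL_SEPARATE,
                        "hypertension_status", levels=(0, 1, 2, 3)),
    ]


def default_lvef_candidates(trpmax_median: float = 18.0,
                            targets: tuple[str, ...] = ("ec50", "t_half_rec"),
                            ) -> list[CovariateCandidate]:
    """Candidate covariate-parameter pairs for the LVEF model.

    The predicted troponin-T peak (and its day-21 variant) enter as
    median-normalized continuous covariates; subject-level values must be
    supplied to the model via ``extra_covariates`` under the names
    ``trpmax`` and ``trp_day21``.
    """
    out = []
    for target in targets:
        out.extend([
            CovariateEffect(f"trpmax_{target}", target, CONTINUOUS_POWER,
                            "trpmax", median=trpmax_median),
            CovariateEffect(f"age_{target}", target, CONTINUOUS_POWER,
                            "age", median=50.0),
            CovariateEffect(f"lvefbl_{target}", target, CONTINUOUS_POWER,
                            "baseline_lvef", median=0.6),
            CovariateEffect(f"gap_{target}", target, CONTINUOUS_POWER,
                            "ac_to_trastuzumab_gap", median=21.0),
            CovariateEffect(f"arm_{target}", target, BINARY_POWER,
                            "treatment_arm"),
            CovariateEffect(f"rtx_{target}", target, BINARY_POWER,
                            "prior_radiotherapy"),
            CovariateEffect(f"cumdose_{target}", target, CONTINUOUS_POWER,
                            "cumulative_dose", median=440.0),
        ])
    return out
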